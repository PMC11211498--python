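"""Domain types and readers/writers for cassette-exon splicing data.

Coordinate convention
---------------------
All genomic intervals are 0-based, half-open (BED convention): an exon
``(start, end)`` covers bases ``start .. end-1``.  Every writer states this in
its header comment.  A cassette-exon ("skipped exon", SE) event consists of an
upstream constitutive exon, the alternative (cassette) exon and a downstream
constitutive exon; "upstream"/"downstream" are in *transcript* orientation, so
on the minus strand the upstream exon has the larger genomic coordinates.

File formats
------------
* events: TSV with columns ``event_id, gene, chrom, strand, up_start, up_end,
  cas_start, cas_end, down_start, down_end``.
* junction counts: either dense TSV (rows = cells, columns = events) or
  MatrixMarket (``.mtx``) triplets with ``<prefix>.cells.txt`` /
  ``<prefix>.events.txt`` index sidecars.
* genome: FASTA.
* motifs: TSV with columns ``name, rbp_gene, pattern`` (IUPAC degenerate
  nucleotide patterns).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.io import mmread, mmwrite
from scipy import sparse

logger = logging.getLogger("isletsplice")

__all__ = [
    "CassetteExonEvent",
    "JunctionCounts",
    "PsiMatrix",
    "MotifDef",
    "REGIONS",
    "IUPAC_CODES",
    "read_events",
    "write_events",
    "read_junction_counts",
    "write_junction_counts",
    "read_fasta",
    "write_fasta",
    "read_motifs",
    "write_motifs",
    "validate_cell_table",
    "read_cell_table",
    "extract_flanking_regions",
    "reverse_complement",
    "write_run_config",
]

#: the four sequence regions used in positional motif maps, in 5'->3'
#: transcript order around the cassette exon
REGIONS = ("upstream_intron", "exon5", "exon3", "downstream_intron")

#: IUPAC degenerate nucleotide codes -> set of concrete bases
IUPAC_CODES: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed."""


@dataclass(frozen=True)
class CassetteExonEvent:
    """One skipped-exon event: flanking exons plus the cassette exon.

    ``up_exon`` and ``down_exon`` are the constitutive exons 5' and 3' of the
    cassette exon in transcript orientation.
    """

    event_id: str
    gene: str
    chrom: str
    strand: str
    up_exon: tuple
    cassette: tuple
    down_exon: tuple

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.event_id}: strand must be '+' or '-', got {self.strand!r}")
        for name, (s, e) in (("up_exon", self.up_exon),
                             ("cassette", self.cassette),
                             ("down_exon", self.down_exon)):
            if s < 0 or e < 0:
                raise ValidationError(f"{self.event_id}: negative coordinate in {name}")
            if s >= e:
                raise ValidationError(
                    f"{self.event_id}: {name} start {s} >= end {e} "
                    "(coordinates are 0-based half-open)")
        if self.strand == "+":
            ordered = (self.up_exon[1] <= self.cassette[0]
                       and self.cassette[1] <= self.down_exon[0])
        else:
            ordered = (self.down_exon[1] <= self.cassette[0]
                       and self.cassette[1] <= self.up_exon[0])
        if not ordered:
            raise ValidationError(
                f"{self.event_id}: exons out of order for strand {self.strand}")


_EVENT_COLUMNS = ["event_id", "gene", "chrom", "strand", "up_start", "up_end",
                  "cas_start", "cas_end", "down_start", "down_end"]


def read_events(path) -> list:
    """Read cassette-exon events from a TSV file.

    Rejects malformed coordinates (naming the offending line) and duplicate
    event ids.
    """
    path = Path(path)
    events, seen = [], set()
    with path.open() as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _EVENT_COLUMNS if c not in header]
                if missing:
                    raise ParseError(f"{path}: missing columns {missing}")
                idx = {c: header.index(c) for c in _EVENT_COLUMNS}
                continue
            try:
                coords = {c: int(fields[idx[c]]) for c in _EVENT_COLUMNS[4:]}
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path} line {lineno}: malformed record ({exc})")
            event_id = fields[idx["event_id"]]
            if event_id in seen:
                raise ValidationError(
                    f"{path} line {lineno}: duplicate event_id {event_id!r}")
            seen.add(event_id)
            try:
                events.append(CassetteExonEvent(
                    event_id=event_id,
                    gene=fields[idx["gene"]],
                    chrom=fields[idx["chrom"]],
                    strand=fields[idx["strand"]],
                    up_exon=(coords["up_start"], coords["up_end"]),
                    cassette=(coords["cas_start"], coords["cas_end"]),
                    down_exon=(coords["down_start"], coords["down_end"]),
                ))
            except ValidationError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}")
    return events


def write_events(events: Iterable[CassetteExonEvent], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# cassette-exon events; coordinates 0-based half-open (BED)\n")
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for ev in events:
            fh.write("\t".join(map(str, [
                ev.event_id, ev.gene, ev.chrom, ev.strand,
                ev.up_exon[0], ev.up_exon[1],
                ev.cassette[0], ev.cassette[1],
                ev.down_exon[0], ev.down_exon[1]])) + "\n")


@dataclass
class JunctionCounts:
    """Paired cells x events matrices of inclusion- and skipping-junction reads.

    ``I`` sums the reads on the two inclusion junctions of each event;
    ``S`` counts reads on the single skipping junction.
    """

    cells: list
    events: list
    I: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        self.I = np.asarray(self.I)
        self.S = np.asarray(self.S)
        shape = (len(self.cells), len(self.events))
        if self.I.shape != shape or self.S.shape != shape:
            raise ValidationError(
                f"count matrices {self.I.shape}/{self.S.shape} inconsistent with "
                f"{len(self.cells)} cells x {len(self.events)} events")
        if (self.I < 0).any() or (self.S < 0).any():
            raise ValidationError("negative junction counts")

    @property
    def total(self) -> np.ndarray:
        """Total junction reads per cell/event, ``I + S``."""
        return self.I + self.S

    def subset_cells(self, cell_ids: Sequence[str]) -> "JunctionCounts":
        pos = {c: i for i, c in enumerate(self.cells)}
        rows = [pos[c] for c in cell_ids]
        return JunctionCounts(list(cell_ids), list(self.events),
                              self.I[rows], self.S[rows])


def _read_count_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".mtx":
        cells_file = path.with_suffix("").with_suffix(".cells.txt")
        events_file = path.with_suffix("").with_suffix(".events.txt")
        for f in (cells_file, events_file):
            if not f.exists():
                raise ParseError(f"index sidecar {f} not found for {path}")
        cells = cells_file.read_text().split()
        events = events_file.read_text().split()
        mat = mmread(str(path))
        mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        if mat.shape != (len(cells), len(events)):
            raise ParseError(
                f"{path}: matrix shape {mat.shape} does not match sidecars "
                f"({len(cells)} cells, {len(events)} events)")
        return pd.DataFrame(mat, index=cells, columns=events)
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_junction_counts(path_i, path_s) -> JunctionCounts:
    """Read aligned inclusion/skipping count matrices (dense TSV or MTX).

    Missing entries in sparse (MTX) input are read as 0.  The two matrices
    must share identical cell and event indices.
    """
    di, ds = _read_count_matrix(path_i), _read_count_matrix(path_s)
    if list(di.index) != list(ds.index) or list(di.columns) != list(ds.columns):
        raise ValidationError(
            "inclusion and skipping matrices have mismatched cell/event indices")
    i_arr = di.to_numpy()
    s_arr = ds.to_numpy()
    if not (np.equal(np.mod(i_arr, 1), 0).all() and np.equal(np.mod(s_arr, 1), 0).all()):
        raise ValidationError("junction counts must be integers")
    return JunctionCounts(list(di.index), list(di.columns),
                          i_arr.astype(np.int64), s_arr.astype(np.int64))


def write_junction_counts(counts: JunctionCounts, path_i, path_s,
                          fmt: str = "tsv") -> None:
    """Write the paired matrices as dense TSV (``fmt='tsv'``) or MTX triplets."""
    if fmt == "tsv":
        for mat, path in ((counts.I, path_i), (counts.S, path_s)):
            pd.DataFrame(mat, index=counts.cells, columns=counts.events) \
                .to_csv(path, sep="\t")
    elif fmt == "mtx":
        for mat, path in ((counts.I, path_i), (counts.S, path_s)):
            path = Path(path)
            mmwrite(str(path), sparse.coo_matrix(mat))
            path.with_suffix("").with_suffix(".cells.txt").write_text(
                "\n".join(counts.cells) + "\n")
            path.with_suffix("").with_suffix(".events.txt").write_text(
                "\n".join(counts.events) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


@dataclass
class PsiMatrix:
    """Cells x events exon-inclusion (psi) values with an explicit missingness mask.

    ``psi`` holds NaN wherever ``observed`` is False (coverage-failed entries);
    observed values lie in [0, 1].
    """

    cells: list
    events: list
    psi: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        shape = (len(self.cells), len(self.events))
        if self.psi.shape != shape or self.observed.shape != shape:
            raise ValidationError("psi/observed shape inconsistent with indices")
        obs = self.psi[self.observed]
        if obs.size and (np.isnan(obs).any() or (obs < 0).any() or (obs > 1).any()):
            raise ValidationError("observed psi values must lie in [0, 1]")
        self.psi = self.psi.copy()
        self.psi[~self.observed] = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.cells, columns=self.events)

    def write(self, psi_path, mask_path) -> None:
        self.to_frame().to_csv(psi_path, sep="\t")
        pd.DataFrame(self.observed.astype(int), index=self.cells,
                     columns=self.events).to_csv(mask_path, sep="\t")

    @classmethod
    def read(cls, psi_path, mask_path) -> "PsiMatrix":
        dpsi = pd.read_csv(psi_path, sep="\t", index_col=0)
        dmask = pd.read_csv(mask_path, sep="\t", index_col=0)
        return cls(list(dpsi.index), list(dpsi.columns),
                   dpsi.to_numpy(), dmask.to_numpy().astype(bool))


@dataclass(frozen=True)
class MotifDef:
    """An RNA-binding-protein motif as an IUPAC degenerate nucleotide pattern."""

    name: str
    rbp_gene: str
    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise ValidationError(f"motif {self.name}: empty pattern")
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise ValidationError(
                f"motif {self.name}: invalid IUPAC letters {sorted(bad)}")


def read_motifs(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [MotifDef(r["name"], r["rbp_gene"], r["pattern"])
            for _, r in df.iterrows()]


def write_motifs(motifs: Iterable[MotifDef], path) -> None:
    pd.DataFrame([{"name": m.name, "rbp_gene": m.rbp_gene, "pattern": m.pattern}
                  for m in motifs]).to_csv(path, sep="\t", index=False)


_CONDITIONS = ("ND", "T2D")


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell-metadata table (cell_id, donor, condition, cell_type).

    ``condition`` is restricted to the two-level ND/T2D factor; cell ids must
    be unique.  Returns the table indexed by cell_id.
    """
    required = {"cell_id", "donor", "condition", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cell table missing columns {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id in cell table")
    bad = set(df["condition"]) - set(_CONDITIONS)
    if bad:
        raise ValidationError(f"condition must be one of {_CONDITIONS}, got {bad}")
    return df.set_index("cell_id", drop=False)


def read_cell_table(path) -> pd.DataFrame:
    return validate_cell_table(pd.read_csv(path, sep="\t", comment="#"))


def read_fasta(path) -> dict:
    """Read a FASTA file into a dict of uppercase sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _slice(seq: str, start: int, end: int, chrom: str) -> str:
    """Contig-bounded slice; warns if the requested region runs off the contig."""
    if start < 0 or end > len(seq):
        warnings.warn(f"region [{start},{end}) truncated at ends of contig {chrom}")
    return seq[max(start, 0):min(end, len(seq))]


def extract_flanking_regions(events: Sequence[CassetteExonEvent],
                             genome,
                             up_len: int = 250,
                             down_len: int = 250,
                             exon_end_len: int = 50) -> pd.DataFrame:
    """Extract the four motif-map regions around each cassette exon.

    Returns a DataFrame indexed by event_id with columns ``upstream_intron``
    (the ``up_len`` intronic bases immediately 5' of the cassette exon),
    ``exon5``/``exon3`` (first/last ``exon_end_len`` exonic bases) and
    ``downstream_intron`` (the ``down_len`` bases immediately 3').  All
    sequences read 5'->3' in transcript orientation; minus-strand events are
    reverse complemented.  Regions are truncated, never padded, when the
    neighbouring constitutive exon (or the contig end) is closer than the
    requested length.
    """
    if isinstance(genome, (str, Path)):
        genome = read_fasta(genome)
    rows = {}
    for ev in events:
        if ev.chrom not in genome:
            raise KeyError(f"{ev.event_id}: chromosome {ev.chrom!r} not in genome")
        seq = genome[ev.chrom]
        cs, ce = ev.cassette
        exon = _slice(seq, cs, ce, ev.chrom)
        if ev.strand == "+":
            up_start = max(cs - up_len, ev.up_exon[1])
            down_end = min(ce + down_len, ev.down_exon[0])
            upstream = _slice(seq, up_start, cs, ev.chrom)
            downstream = _slice(seq, ce, down_end, ev.chrom)
            exon5 = exon[:exon_end_len]
            exon3 = exon[-exon_end_len:]
        else:
            # transcript-upstream intron lies at higher genomic coordinates
            up_end = min(ce + up_len, ev.up_exon[0])
            down_start = max(cs - down_len, ev.down_exon[1])
            upstream = reverse_complement(_slice(seq, ce, up_end, ev.chrom))
            downstream = reverse_complement(_slice(seq, down_start, cs, ev.chrom))
            rc = reverse_complement(exon)
            exon5 = rc[:exon_end_len]
            exon3 = rc[-exon_end_len:]
        rows[ev.event_id] = {"upstream_intron": upstream, "exon5": exon5,
                             "exon3": exon3, "downstream_intron": downstream}
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=list(REGIONS))


def write_run_config(outdir, config: Mapping) -> None:
    """Echo the run configuration as JSON into an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "run_config.json").open("w") as fh:
        json.dump(config, fh, indent=2, default=str)
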