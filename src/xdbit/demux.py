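"""Reads-to-counts: barcode demultiplexing and UMI collapsing.

Raw paired-end reads from a deterministic-barcoding run carry the cDNA
sequence on read 1 and, on read 2, a unique molecular identifier (UMI)
plus up to three barcodes: the x-barcode (vertical channel / column), the
y-barcode (horizontal channel / row) and, in xDBiT mode, the z-barcode
identifying the reverse-transcription well.  This module turns such read
pairs into a spot x gene matrix of UMI counts:

1. ``extract_barcodes``     - cut UMI and barcode fields out of read 2,
2. ``correct_and_assign``   - match each field against the barcode legend
                              allowing a bounded number of mismatches,
3. ``filter_crosstalk``     - drop reads whose well barcode contradicts
                              the library they were sequenced from,
4. ``assign_gene``          - map read 1 to a gene of the toy reference,
5. ``digital_expression``   - collapse UMIs per (spot, gene) and count.

Reads are processed strictly one at a time; no per-read decision depends
on any other read, so the stream can be chunked or parallelised freely.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .chip_geometry import ChipLayout, spot_center

__all__ = [
    "ReadSegment",
    "ReadLayout",
    "BarcodeLegend",
    "BarcodeAssignment",
    "CountMatrix",
    "HammingMatcher",
    "ToyReference",
    "extract_barcodes",
    "correct_and_assign",
    "filter_crosstalk",
    "assign_gene",
    "collapse_umis",
    "digital_expression",
    "rna_metrics",
    "reads_to_counts",
    "default_read_layout",
]

VALID = "valid"
SHORT = "short"
INVALID_X = "invalid_x"
INVALID_Y = "invalid_y"
INVALID_Z = "invalid_z"
CROSSTALK = "crosstalk"
STATUSES = (VALID, SHORT, INVALID_X, INVALID_Y, INVALID_Z, CROSSTALK)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# read 2 layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSegment:
    """One functional stretch of read 2."""

    role: str  # umi | x_barcode | y_barcode | z_barcode | linker | ignore
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class ReadLayout:
    """Ordered, non-overlapping segments of read 2.

    Exactly one segment per barcode role; the z segment is optional
    (absent in plain DBiT mode).  Default geometry: 10 nt UMI, then the
    8 nt x-barcode, a linker, the 8 nt y-barcode, a linker, and the 8 nt
    z-barcode.
    """

    segments: tuple[ReadSegment, ...]

    def __post_init__(self) -> None:
        spans = sorted((s.start, s.end) for s in self.segments)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("read layout segments overlap")
        for role in ("umi", "x_barcode", "y_barcode"):
            if sum(s.role == role for s in self.segments) != 1:
                raise ValueError(f"layout needs exactly one {role} segment")
        if sum(s.role == "z_barcode" for s in self.segments) > 1:
            raise ValueError("at most one z_barcode segment")

    def segment(self, role: str) -> ReadSegment | None:
        for s in self.segments:
            if s.role == role:
                return s
        return None

    @property
    def has_z(self) -> bool:
        return self.segment("z_barcode") is not None

    @property
    def min_read_length(self) -> int:
        return max(
            s.end
            for s in self.segments
            if s.role in ("umi", "x_barcode", "y_barcode", "z_barcode")
        )


def default_read_layout(
    umi_length: int = 10,
    barcode_length: int = 8,
    linker_length: int = 30,
    with_z: bool = True,
) -> ReadLayout:
    """UMI - x - linker - y - linker - [z] layout with the given sizes."""
    pos = 0
    segs = [ReadSegment("umi", pos, umi_length)]
    pos += umi_length
    segs.append(ReadSegment("x_barcode", pos, barcode_length))
    pos += barcode_length
    segs.append(ReadSegment("linker", pos, linker_length))
    pos += linker_length
    segs.append(ReadSegment("y_barcode", pos, barcode_length))
    pos += barcode_length
    if with_z:
        segs.append(ReadSegment("linker", pos, linker_length))
        pos += linker_length
        segs.append(ReadSegment("z_barcode", pos, barcode_length))
    return ReadLayout(tuple(segs))


# ---------------------------------------------------------------------------
# barcode legend
# ---------------------------------------------------------------------------

def _check_sequences(seqs: Iterable[str], axis: str) -> None:
    seen = set()
    for s in seqs:
        if not s or set(s) - set(_BASES):
            raise ValueError(f"{axis} barcode {s!r} is not uppercase ACGT")
        if s in seen:
            raise ValueError(f"duplicate {axis} barcode {s!r}")
        seen.add(s)


@dataclass(frozen=True)
class BarcodeLegend:
    """Sequence -> index maps for the x and y axes and sequence -> well for z.

    Several z-barcodes may map to the same well (the RevT primer mixes
    contain four barcodes per well by default).
    """

    x: dict[str, int]
    y: dict[str, int]
    z: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_sequences(self.x, "x")
        _check_sequences(self.y, "y")
        _check_sequences(self.z, "z")

    @property
    def wells(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.z.values():
            seen.setdefault(w)
        return list(seen)

    # -- CSV round trip (columns: axis, sequence, index_or_well) ------------

    def to_csv(self, path) -> None:
        rows = (
            [("x", s, i) for s, i in self.x.items()]
            + [("y", s, i) for s, i in self.y.items()]
            + [("z", s, w) for s, w in self.z.items()]
        )
        pd.DataFrame(rows, columns=["axis", "sequence", "index_or_well"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "BarcodeLegend":
        df = pd.read_csv(path, dtype=str)
        x = {
            r.sequence: int(r.index_or_well)
            for r in df[df.axis == "x"].itertuples()
        }
        y = {
            r.sequence: int(r.index_or_well)
            for r in df[df.axis == "y"].itertuples()
        }
        z = {r.sequence: r.index_or_well for r in df[df.axis == "z"].itertuples()}
        return cls(x=x, y=y, z=z)


# ---------------------------------------------------------------------------
# Hamming matching
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(c1 != c2 for c1, c2 in zip(a, b))


class HammingMatcher:
    """Match a query against a barcode whitelist within ``max_hamming``.

    A query resolves iff exactly one legend entry attains the minimal
    distance and that distance is <= max_hamming; ties between entries are
    rejected even when they map to the same value.  For max_hamming <= 1
    matching is a precomputed O(1) table lookup over all single-mismatch
    variants; larger radii fall back to a linear scan.
    """

    _AMBIGUOUS = object()

    def __init__(self, legend: Mapping[str, object], max_hamming: int = 1):
        if max_hamming < 0:
            raise ValueError("max_hamming must be >= 0")
        self.legend = dict(legend)
        self.max_hamming = max_hamming
        self._table: dict[str, object] | None = None
        if max_hamming <= 1 and self.legend:
            self._table = self._build_table()

    def _build_table(self) -> dict[str, object]:
        dist: dict[str, int] = {}
        table: dict[str, object] = {}
        for seq, value in self.legend.items():
            variants = [(seq, 0)]
            if self.max_hamming >= 1:
                for i, orig in enumerate(seq):
                    for b in _BASES:
                        if b != orig:
                            variants.append((seq[:i] + b + seq[i + 1 :], 1))
            for var, d in variants:
                if var not in table or d < dist[var]:
                    table[var] = value
                    dist[var] = d
                elif d == dist[var]:
                    # equal-distance hit from a different legend entry
                    table[var] = self._AMBIGUOUS
        return table

    def match(self, query: str) -> object | None:
        """Resolved legend value, or None for no/ambiguous match."""
        if self._table is not None:
            hit = self._table.get(query)
            return None if hit is self._AMBIGUOUS else hit
        best_d, best_val, tie = self.max_hamming + 1, None, False
        for seq, value in self.legend.items():
            if len(seq) != len(query):
                continue
            d = hamming(seq, query)
            if d < best_d:
                best_d, best_val, tie = d, value, False
            elif d == best_d:
                tie = True
        if tie or best_d > self.max_hamming:
            return None
        return best_val


# ---------------------------------------------------------------------------
# per-read operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawBarcodeFields:
    """Uncorrected substrings cut from read 2."""

    umi: str | None
    x_seq: str | None
    y_seq: str | None
    z_seq: str | None
    short: bool = False


@dataclass(frozen=True)
class BarcodeAssignment:
    read_id: str
    umi: str | None
    x_idx: int | None
    y_idx: int | None
    well_id: str | None
    status: str


def extract_barcodes(read2_sequence: str, layout: ReadLayout) -> RawBarcodeFields:
    """Cut the UMI and barcode substrings out of read 2; no correction."""
    if len(read2_sequence) < layout.min_read_length:
        return RawBarcodeFields(None, None, None, None, short=True)
    seq = read2_sequence.upper()

    def cut(role: str) -> str | None:
        seg = layout.segment(role)
        return None if seg is None else seq[seg.start : seg.end]

    return RawBarcodeFields(
        umi=cut("umi"),
        x_seq=cut("x_barcode"),
        y_seq=cut("y_barcode"),
        z_seq=cut("z_barcode"),
    )


def correct_and_assign(
    raw: RawBarcodeFields,
    legend: BarcodeLegend,
    max_hamming: int = 1,
    read_id: str = "",
    matchers: tuple[HammingMatcher, HammingMatcher, HammingMatcher] | None = None,
    require_z: bool | None = None,
) -> BarcodeAssignment:
    """Resolve raw barcode fields against the legend.

    A read is valid iff its x- and y-barcodes (and the z-barcode when the
    layout defines one) each match a unique legend entry within
    ``max_hamming`` mismatches.  The first failing axis determines the
    status, checked in the order short, x, y, z.
    """
    if raw.short:
        return BarcodeAssignment(read_id, None, None, None, None, SHORT)
    if matchers is None:
        matchers = (
            HammingMatcher(legend.x, max_hamming),
            HammingMatcher(legend.y, max_hamming),
            HammingMatcher(legend.z, max_hamming),
        )
    mx, my, mz = matchers
    x_idx = mx.match(raw.x_seq) if raw.x_seq is not None else None
    if x_idx is None:
        return BarcodeAssignment(read_id, raw.umi, None, None, None, INVALID_X)
    y_idx = my.match(raw.y_seq) if raw.y_seq is not None else None
    if y_idx is None:
        return BarcodeAssignment(read_id, raw.umi, x_idx, None, None, INVALID_Y)
    if require_z is None:
        require_z = raw.z_seq is not None
    well_id = None
    if raw.z_seq is not None:
        well_id = mz.match(raw.z_seq)
    if require_z and well_id is None:
        return BarcodeAssignment(read_id, raw.umi, x_idx, y_idx, None, INVALID_Z)
    return BarcodeAssignment(read_id, raw.umi, x_idx, y_idx, well_id, VALID)


def filter_crosstalk(
    assignment: BarcodeAssignment,
    library_well: str | None,
    expected_wells: Mapping[str, Sequence[str]] | None = None,
) -> BarcodeAssignment:
    """Flag reads whose z-derived well contradicts their library.

    Each sequencing library comes from one physical well; a valid read
    whose z-barcode resolves to a different well is a cross-contamination
    ("crosstalk") and is flagged for removal.  With no z information, or
    no library annotation, this is a pass-through.
    """
    if assignment.status != VALID or assignment.well_id is None:
        return assignment
    if library_well is None:
        return assignment
    allowed = (
        set(expected_wells[library_well])
        if expected_wells is not None and library_well in expected_wells
        else {library_well}
    )
    if assignment.well_id not in allowed:
        return replace(assignment, status=CROSSTALK)
    return assignment


# ---------------------------------------------------------------------------
# toy gene assignment
# ---------------------------------------------------------------------------

class ToyReference:
    """Exact-prefix gene assigner over a small synthetic transcript set.

    The reference is a set of transcript records, each tagged with a gene,
    a transcript name and a region (exonic or intronic).  A read is
    assigned to a gene iff its first ``min_prefix`` bases occur in the
    records of exactly one gene; reads matching no record or records of
    several genes stay unassigned.  This stands in for genome alignment in
    a hermetic pipeline; real data can instead supply a pre-tagged read
    table (read_id -> gene, region).
    """

    def __init__(
        self,
        records: Sequence[tuple[str, str, str, str]],
        min_prefix: int = 30,
    ):
        # records: (gene, transcript, region, sequence)
        if not records:
            raise ValueError("empty reference")
        if min_prefix < 1:
            raise ValueError("min_prefix must be positive")
        for gene, tx, region, seq in records:
            if len(seq) < min_prefix:
                raise ValueError(
                    f"reference sequence {gene}|{tx} shorter than min_prefix"
                )
            if region not in ("exonic", "intronic"):
                raise ValueError(f"unknown region tag {region!r}")
        self.records = list(records)
        self.min_prefix = min_prefix
        self._index: dict[str, set[tuple[str, str]]] = {}
        k = min_prefix
        for gene, _tx, region, seq in self.records:
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], set()).add((gene, region))

    @classmethod
    def from_fasta(cls, path, min_prefix: int = 30) -> "ToyReference":
        """Load from FASTA with headers formatted ``gene|transcript|region``."""
        from Bio import SeqIO

        records = []
        with _open_maybe_gzip(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                gene, tx, region = rec.id.split("|")
                records.append((gene, tx, region, str(rec.seq).upper()))
        return cls(records, min_prefix=min_prefix)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gene, tx, region, seq in self.records:
                fh.write(f">{gene}|{tx}|{region}\n{seq}\n")

    def lookup(self, read1_sequence: str) -> tuple[str | None, str | None]:
        """(gene, region) for a read, or (None, None) if unassigned."""
        if len(read1_sequence) < self.min_prefix:
            return None, None
        hits = self._index.get(read1_sequence[: self.min_prefix].upper())
        if not hits:
            return None, None
        genes = {g for g, _ in hits}
        if len(genes) != 1:
            return None, None
        regions = {r for _, r in hits}
        region = "exonic" if "exonic" in regions else "intronic"
        return next(iter(genes)), region


def assign_gene(
    read1_sequence: str, reference: ToyReference, min_prefix: int | None = None
) -> tuple[str | None, str | None]:
    """Assign a read to a gene by unique exact prefix match.

    ``min_prefix`` other than the reference's indexed prefix length
    requires rebuilding the index, so it must match when given.
    """
    if min_prefix is not None and min_prefix != reference.min_prefix:
        raise ValueError(
            "min_prefix differs from the reference index; rebuild the reference"
        )
    return reference.lookup(read1_sequence)


# ---------------------------------------------------------------------------
# UMI collapsing and the count matrix
# ---------------------------------------------------------------------------

def collapse_umis(umis: Sequence[str]) -> int:
    """Number of UMI clusters under single-linkage at Hamming distance <= 1.

    Mirrors the edit-distance-1 collapse of digital-expression counting at
    fixed UMI length: duplicate reads and single-base sequencing errors of
    one molecule merge into one cluster.  Union-find over all Hamming-1
    pairs of the distinct UMIs; order-independent by construction.
    """
    uniq = sorted(set(umis))
    n = len(uniq)
    if n <= 1:
        return n
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # neighbour table keyed by UMI with one wildcard position; two UMIs at
    # Hamming distance 1 share exactly one masked form
    masked: dict[str, list[int]] = {}
    for idx, u in enumerate(uniq):
        for p in range(len(u)):
            masked.setdefault(u[:p] + "." + u[p + 1 :], []).append(idx)
    for group in masked.values():
        for j in group[1:]:
            union(group[0], j)
    return len({find(i) for i in range(n)})


def _spot_id(well_id: str, x_idx: int, y_idx: int) -> str:
    return f"{well_id}_x{x_idx:02d}_y{y_idx:02d}"


@dataclass
class CountMatrix:
    """Spot x gene UMI counts plus per-spot metadata.

    ``counts`` is an integer DataFrame (rows = spot ids, columns = genes);
    ``spots`` is indexed identically and carries well_id, x_idx, y_idx and
    any metadata later stages attach (µm coordinates, totals, tissue flag).
    """

    counts: pd.DataFrame
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.spots.index):
            raise ValueError("counts and spot metadata indices differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    def attach_grid_coordinates(self, layout: ChipLayout) -> None:
        """Fill x_um / y_um spot metadata from the chip layout."""
        xs, ys = [], []
        for row in self.spots.itertuples():
            cx, cy = spot_center(layout, row.well_id, int(row.x_idx), int(row.y_idx))
            xs.append(cx)
            ys.append(cy)
        self.spots["x_um"] = xs
        self.spots["y_um"] = ys

    def pseudobulk(self) -> pd.Series:
        """Gene-wise sum over all spots."""
        return self.counts.sum(axis=0)

    def equals_counts(self, other: "CountMatrix") -> bool:
        """Count equality on the union of spots and genes (zero-filled)."""
        rows = self.counts.index.union(other.counts.index)
        cols = self.counts.columns.union(other.counts.columns)
        a = self.counts.reindex(index=rows, columns=cols, fill_value=0)
        b = other.counts.reindex(index=rows, columns=cols, fill_value=0)
        return bool((a.to_numpy() == b.to_numpy()).all())

    # -- I/O ---------------------------------------------------------------

    def to_mtx(self, out_dir) -> None:
        """MatrixMarket counts with spot and gene TSV sidecars."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            out / "counts.mtx", scipy.sparse.csr_matrix(self.counts.to_numpy())
        )
        self.spots.to_csv(out / "spots.tsv", sep="\t")
        pd.Series(self.genes, name="gene").to_csv(
            out / "genes.tsv", sep="\t", index=False
        )

    @classmethod
    def from_mtx(cls, out_dir) -> "CountMatrix":
        out = Path(out_dir)
        m = scipy.io.mmread(out / "counts.mtx").toarray().astype(int)
        spots = pd.read_csv(out / "spots.tsv", sep="\t", index_col=0)
        genes = pd.read_csv(out / "genes.tsv", sep="\t")["gene"].tolist()
        return cls(pd.DataFrame(m, index=spots.index, columns=genes), spots)

    def to_anndata(self):
        """AnnData view with spatial coordinates in ``obsm['spatial']``."""
        import anndata

        adata = anndata.AnnData(
            X=scipy.sparse.csr_matrix(self.counts.to_numpy(dtype=np.float32)),
            obs=self.spots.copy(),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )
        if {"x_um", "y_um"} <= set(self.spots.columns):
            adata.obsm["spatial"] = self.spots[["x_um", "y_um"]].to_numpy()
        return adata


def digital_expression(
    records: pd.DataFrame, include_intronic: bool = True
) -> CountMatrix:
    """Collapse UMIs of gene-assigned reads into a count matrix.

    ``records`` needs columns well_id, x_idx, y_idx, gene, umi and
    optionally region; rows with missing genes are ignored.  Within every
    (spot, gene) group the count is the number of Hamming-1 single-linkage
    UMI clusters.  The result is independent of the input row order.
    """
    df = records.dropna(subset=["gene"]).copy()
    if "region" in df.columns and not include_intronic:
        df = df[df["region"] != "intronic"]
    if df.empty:
        empty = pd.DataFrame(
            index=pd.Index([], name="spot_id"), columns=[], dtype=int
        )
        meta = pd.DataFrame(
            index=empty.index, columns=["well_id", "x_idx", "y_idx"]
        )
        return CountMatrix(empty, meta)
    df["spot_id"] = [
        _spot_id(w, int(x), int(y))
        for w, x, y in zip(df["well_id"], df["x_idx"], df["y_idx"])
    ]
    grouped = (
        df.groupby(["spot_id", "gene"], sort=True)["umi"]
        .apply(lambda u: collapse_umis(list(u)))
        .rename("count")
    )
    counts = grouped.unstack(fill_value=0).astype(int)
    counts.index.name = "spot_id"
    counts.columns = [str(c) for c in counts.columns]
    meta_src = df.drop_duplicates("spot_id").set_index("spot_id")
    spots = meta_src.loc[counts.index, ["well_id", "x_idx", "y_idx"]].copy()
    spots["x_idx"] = spots["x_idx"].astype(int)
    spots["y_idx"] = spots["y_idx"].astype(int)
    reads_per_spot = df.groupby("spot_id").size()
    spots["total_reads"] = reads_per_spot.reindex(counts.index).fillna(0).astype(int)
    spots["total_umis"] = counts.sum(axis=1)
    spots["n_genes"] = (counts > 0).sum(axis=1)
    return CountMatrix(counts, spots)


# ---------------------------------------------------------------------------
# metrics and the full pipeline
# ---------------------------------------------------------------------------

def rna_metrics(
    records: pd.DataFrame,
    matrix: CountMatrix,
    total_reads: int | None = None,
) -> dict:
    """Per-run summary: status counts, per-spot medians, depth-normalised rates.

    Depth normalisation follows the convention of reporting UMI and gene
    counts per spot per 10^6 sequenced reads.
    """
    if total_reads is None:
        total_reads = len(records)
    status_counts = records["status"].value_counts().to_dict() if "status" in records else {}
    umis = matrix.spots["total_umis"] if matrix.n_spots else pd.Series(dtype=float)
    genes = matrix.spots["n_genes"] if matrix.n_spots else pd.Series(dtype=float)
    med_umis = float(umis.median()) if len(umis) else 0.0
    med_genes = float(genes.median()) if len(genes) else 0.0
    scale = 1e6 / total_reads if total_reads else 0.0
    intronic = 0.0
    if "region" in records.columns:
        assigned = records.dropna(subset=["gene"]) if "gene" in records else records
        if len(assigned):
            intronic = float((assigned["region"] == "intronic").mean())
    return {
        "total_reads": int(total_reads),
        "status_counts": {k: int(v) for k, v in status_counts.items()},
        "valid_fraction": (
            float(status_counts.get(VALID, 0)) / total_reads if total_reads else 0.0
        ),
        "median_umis_per_spot": med_umis,
        "median_genes_per_spot": med_genes,
        "median_umis_per_spot_per_1e6_reads": med_umis * scale,
        "median_genes_per_spot_per_1e6_reads": med_genes * scale,
        "intronic_fraction": intronic,
    }


def _open_maybe_gzip(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ file (plain or gzip)."""
    from Bio import SeqIO

    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def reads_to_counts(
    r1_path,
    r2_path,
    legend: BarcodeLegend,
    read_layout: ReadLayout | None = None,
    chip_layout: ChipLayout | None = None,
    reference: ToyReference | None = None,
    tagged_reads: Mapping[str, tuple[str, str]] | None = None,
    mode: str = "xdbit",
    library_well: str | None = None,
    expected_wells: Mapping[str, Sequence[str]] | None = None,
    max_hamming: int = 1,
    include_intronic: bool = True,
    spatial_only: bool = False,
) -> tuple[CountMatrix, dict, pd.DataFrame]:
    """Run the full reads-to-counts stage on one library.

    Parameters
    ----------
    r1_path, r2_path
        Paired FASTQ files: read 1 = cDNA, read 2 = UMI + barcodes.
    legend
        Barcode legend; in ``mode='dbit'`` the z axis is ignored.
    reference, tagged_reads
        Gene source: a toy transcript reference, or a pre-tagged mapping
        read_id -> (gene, region).  ``spatial_only=True`` skips gene
        assignment entirely (barcode bookkeeping only, as used for the
        cross-contamination analysis).
    library_well
        Physical well this library was retrieved from; enables the
        crosstalk filter when z-barcodes are present.

    Returns
    -------
    (count_matrix, metrics, read_records) where ``read_records`` has one
    row per input read pair with its resolved fields and status.
    """
    if read_layout is None:
        read_layout = default_read_layout(with_z=(mode == "xdbit"))
    if mode not in ("xdbit", "dbit"):
        raise ValueError(f"unknown mode {mode!r}")
    use_z = mode == "xdbit" and read_layout.has_z
    matchers = (
        HammingMatcher(legend.x, max_hamming),
        HammingMatcher(legend.y, max_hamming),
        HammingMatcher(legend.z if use_z else {}, max_hamming),
    )
    rows = []
    for (rid1, seq1), (rid2, seq2) in zip(iter_fastq(r1_path), iter_fastq(r2_path)):
        raw = extract_barcodes(seq2, read_layout)
        if not use_z:
            raw = replace(raw, z_seq=None)
        a = correct_and_assign(
            raw, legend, max_hamming, read_id=rid2, matchers=matchers,
            require_z=use_z,
        )
        if use_z:
            a = filter_crosstalk(a, library_well, expected_wells)
        gene, region = None, None
        if a.status == VALID and not spatial_only:
            if tagged_reads is not None:
                gene, region = tagged_reads.get(rid1, (None, None))
            elif reference is not None:
                gene, region = reference.lookup(seq1)
        rows.append(
            (rid1, a.status, a.x_idx, a.y_idx, a.well_id, a.umi, gene, region)
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "read_id", "status", "x_idx", "y_idx", "well_id", "umi", "gene",
            "region",
        ],
    )
    if library_well is not None:
        records["library_well"] = library_well
    valid = records[records["status"] == VALID].copy()
    if not use_z:
        valid["well_id"] = library_well if library_well is not None else "well0"
    matrix = digital_expression(valid, include_intronic=include_intronic)
    if chip_layout is not None and matrix.n_spots:
        matrix.attach_grid_coordinates(chip_layout)
    metrics = rna_metrics(records, matrix)
    return matrix, metrics, records


def write_metrics_json(metrics: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2)
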