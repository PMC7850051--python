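"""Readers and writers for the formats the pipeline touches.

Supported formats
-----------------
* ``sync``  -- tab-separated pooled allele counts, one row per site:
  chromosome, 1-based position, reference base, then one ``A:T:C:G:N:del``
  colon-separated sextuplet per population.
* GFF3 gene annotations (gene/mRNA/CDS), read into :class:`GeneModel`.
* FASTA reference sequences.
* TSV reports with a fixed column schema and fixed float precision.

All coordinates are 1-based inclusive. ``N`` and ``del`` counts are parsed
but excluded from coverage and from every downstream statistic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: order of the count fields in a sync column
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: bases that contribute to coverage (index into the sextuplet)
BASES = ("A", "T", "C", "G")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_ALLOWED_REF = set("ACGTN")


class SyncFormatError(ValueError):
    """Raised when a sync file violates the expected layout."""


class GffFormatError(ValueError):
    """Raised when a GFF3 file cannot be interpreted as gene models."""


@dataclass
class PooledSiteCounts:
    """Per-site nucleotide counts for every sequenced pool.

    ``counts`` has shape ``(n_populations, 6)`` in ``A,T,C,G,N,del`` order.
    """

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_populations, 6)")
        if (self.counts < 0).any():
            raise ValueError(f"negative count at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _ALLOWED_REF:
            raise ValueError(f"reference base {self.ref!r} not in ACGTN")

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-population A+T+C+G coverage (N and del excluded)."""
        return self.counts[:, :4].sum(axis=1)


@dataclass
class GeneModel:
    """A protein-coding gene model: ordered, non-overlapping CDS intervals."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    name: str = ""
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id}: no CDS intervals")
        ivs = [(int(s), int(e)) for s, e in self.cds_intervals]
        ivs.sort()
        for (s, e) in ivs:
            if e < s or s < 1:
                raise ValueError(f"gene {self.gene_id}: bad interval ({s},{e})")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"gene {self.gene_id}: overlapping CDS intervals "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        self.cds_intervals = ivs
        if self.complete and self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: complete CDS length {self.cds_length} "
                "not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_intervals)


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def _parse_sextuplet(field_: str, lineno: int) -> list[int]:
    parts = field_.split(":")
    if len(parts) != 6:
        raise SyncFormatError(
            f"line {lineno}: count field {field_!r} does not have 6 "
            "colon-separated entries"
        )
    try:
        vals = [int(p) for p in parts]
    except ValueError as exc:
        raise SyncFormatError(
            f"line {lineno}: non-integer count in field {field_!r}"
        ) from exc
    if any(v < 0 for v in vals):
        raise SyncFormatError(f"line {lineno}: negative count in {field_!r}")
    return vals


def read_sync(path: str | os.PathLike, n_populations: int) -> Iterator[PooledSiteCounts]:
    """Stream :class:`PooledSiteCounts` records from a sync file.

    Malformed rows raise :class:`SyncFormatError` naming the line number;
    they are never silently skipped.
    """
    if n_populations < 1:
        raise ValueError("n_populations must be >= 1")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_populations:
                raise SyncFormatError(
                    f"line {lineno}: expected {3 + n_populations} columns, "
                    f"found {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncFormatError(
                    f"line {lineno}: non-integer position {pos_s!r}"
                ) from exc
            counts = np.array(
                [_parse_sextuplet(f, lineno) for f in fields[3:]], dtype=np.int64
            )
            try:
                yield PooledSiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts)
            except ValueError as exc:
                raise SyncFormatError(f"line {lineno}: {exc}") from exc


def write_sync(records: Iterable[PooledSiteCounts], path: str | os.PathLike) -> None:
    """Write records in canonical sync layout (inverse of :func:`read_sync`)."""
    with open(path, "w") as fh:
        for rec in records:
            cols = [":".join(str(v) for v in row) for row in rec.counts]
            fh.write("\t".join([rec.chrom, str(rec.pos), rec.ref] + cols) + "\n")


@dataclass
class SyncMatrix:
    """Column-oriented view of a sync file for vectorised computation.

    ``counts`` has shape ``(n_sites, n_populations, 6)``.
    """

    chroms: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.pos.shape[0]

    @property
    def n_populations(self) -> int:
        return self.counts.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        """(n_sites, n_populations) A+T+C+G coverage."""
        return self.counts[:, :, :4].sum(axis=2)

    def iter_records(self) -> Iterator[PooledSiteCounts]:
        for i in range(self.n_sites):
            yield PooledSiteCounts(
                chrom=str(self.chroms[i]),
                pos=int(self.pos[i]),
                ref=str(self.ref[i]),
                counts=self.counts[i],
            )


def read_sync_matrix(path: str | os.PathLike, n_populations: int) -> SyncMatrix:
    """Read a whole sync file into arrays (fast path used by the pipeline)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, na_filter=False,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return SyncMatrix(
            chroms=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object),
            counts=np.zeros((0, n_populations, 6), dtype=np.int64),
        )
    if df.shape[1] != 3 + n_populations:
        raise SyncFormatError(
            f"expected {3 + n_populations} columns, found {df.shape[1]}"
        )
    try:
        pos = df[1].to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise SyncFormatError(f"non-integer position column: {exc}") from exc
    ref = df[2].to_numpy(dtype=object)
    bad_ref = ~np.isin(ref.astype(str), list(_ALLOWED_REF))
    if bad_ref.any():
        i = int(np.flatnonzero(bad_ref)[0])
        raise SyncFormatError(f"line {i + 1}: reference base {ref[i]!r} not in ACGTN")
    n = len(df)
    counts = np.empty((n, n_populations, 6), dtype=np.int64)
    for p in range(n_populations):
        split = df[3 + p].str.split(":", expand=True)
        if split.shape[1] != 6 or split.isna().any().any():
            raise SyncFormatError(
                f"population column {p + 1}: count fields are not "
                "6-entry colon-separated sextuplets"
            )
        try:
            counts[:, p, :] = split.to_numpy(dtype=np.int64)
        except ValueError as exc:
            raise SyncFormatError(
                f"population column {p + 1}: non-integer count: {exc}"
            ) from exc
    if (counts < 0).any():
        raise SyncFormatError("negative count encountered")
    if (pos < 1).any():
        raise SyncFormatError("positions must be >= 1")
    return SyncMatrix(
        chroms=df[0].to_numpy(dtype=object), pos=pos, ref=ref, counts=counts
    )


def write_sync_matrix(mat: SyncMatrix, path: str | os.PathLike) -> None:
    """Vectorised sync writer (inverse of :func:`read_sync_matrix`)."""
    cols = {0: pd.Series(mat.chroms), 1: pd.Series(mat.pos), 2: pd.Series(mat.ref)}
    for p in range(mat.n_populations):
        sub = mat.counts[:, p, :]
        s = sub[:, 0].astype(str).astype(object)
        for a in range(1, 6):
            s = s + ":" + sub[:, a].astype(str)
        cols[3 + p] = pd.Series(s)
    pd.DataFrame(cols).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Read GFF3 gene models: one :class:`GeneModel` per mRNA feature.

    CDS rows must carry a ``Parent`` attribute linking them to an mRNA;
    overlapping CDS intervals within one model are an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    # validate CDS parentage before assembling models
    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes:
            raise GffFormatError(
                f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no Parent attribute"
            )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        cds_list = list(db.children(mrna, featuretype="CDS"))
        if not cds_list:
            continue
        intervals = sorted((c.start, c.end) for c in cds_list)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise GffFormatError(
                    f"mRNA {mrna.id}: overlapping CDS ({s1},{e1}) and ({s2},{e2})"
                )
        name = mrna.attributes.get("Name", [""])[0]
        total = sum(e - s + 1 for s, e in intervals)
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                cds_intervals=intervals,
                name=name,
                complete=(total % 3 == 0),
            )
        )
    return models


def write_gff(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as minimal GFF3 (gene + mRNA + CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            gid = f"gene-{m.gene_id}"
            fh.write(
                f"{m.chrom}\tpoolsweep\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={gid};Name={m.name}\n"
            )
            fh.write(
                f"{m.chrom}\tpoolsweep\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent={gid};Name={m.name}\n"
            )
            for i, (s, e) in enumerate(m.cds_intervals):
                phase = _cds_phase(m, i)
                fh.write(
                    f"{m.chrom}\tpoolsweep\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id}\n"
                )


def _cds_phase(m: GeneModel, idx: int) -> int:
    if m.strand == "+":
        upstream = sum(e - s + 1 for s, e in m.cds_intervals[:idx])
    else:
        upstream = sum(e - s + 1 for s, e in m.cds_intervals[idx + 1:])
    return (3 - upstream % 3) % 3


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into a dict of uppercase sequences keyed by id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

REPORT_SCHEMAS: dict[str, tuple[str, ...]] = {
    "window_stats": ("chrom", "start", "end", "pi", "thetaW", "tajd",
                     "snps", "covered_frac"),
    "gene_pi": ("gene_id", "pi", "n_snps", "mean_coverage", "usable"),
    "sweep_regions": ("chrom", "start", "end", "populations", "min_pi",
                      "mean_pi", "n_windows", "flank_pi_left", "flank_pi_right",
                      "genes_contained"),
    "fst_snp": ("chrom", "pos", "pop_pair", "fst_classical", "fst_anova"),
    "fst_window": ("chrom", "start", "end", "pop_pair", "fst_classical",
                   "fst_anova"),
    "fst_summary": ("pop_pair", "scope", "fst_classical", "fst_anova", "n_snps"),
    "pca_outliers": ("chrom", "pos", "d2", "p_value", "q_value"),
    "variants": ("chrom", "pos", "ref", "alt", "gene_id", "consequence",
                 "aa_change", "conservative", "fractions"),
    "probit": ("population", "slope", "intercept", "lc50", "ci_low", "ci_high",
               "heterogeneity", "flagged"),
}

_FLOAT_FMT = "{:.6f}"


def _format_value(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "NA"
        return _FLOAT_FMT.format(float(v))
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return str(v)


def write_report(records: Iterable, path: str | os.PathLike, schema: str) -> None:
    """Write records as a TSV with a header row and 6-decimal floats.

    ``records`` may be dicts, dataclass instances, or objects with matching
    attributes; ``schema`` names one of :data:`REPORT_SCHEMAS`. Rows are
    written in input order, so callers control determinism by sorting.
    """
    if schema not in REPORT_SCHEMAS:
        raise KeyError(f"unknown report schema {schema!r}")
    columns = REPORT_SCHEMAS[schema]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            if isinstance(rec, dict):
                get = rec.get
            else:
                get = lambda c, _r=rec: getattr(_r, c, None)  # noqa: E731
            fh.write("\t".join(_format_value(get(c)) for c in columns) + "\n")
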