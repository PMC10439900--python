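"""Reads -> normalized site-depth matrix.

The preprocessing contract mirrors the assay's data processing: drop short or
mate-less reads and reads with an ambiguous UMI, assign reads to SacII sites
by their 5' terminus, collapse PCR duplicates by directional UMI clustering,
classify molecules as on-target if their genome-facing read begins "GCGG",
and normalize per-sample site depths by a trimmed mean (average depth over
all sites excluding 10% outliers, 5% per tail).

Alignment itself is externalized: reads carry positions either from the
simulator's truth table or from a coordinate-sorted SAM/BAM produced by an
external aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import SacIISiteTable

ON_TARGET_PREFIX = "GCGG"
UMI_LENGTH = 10
BACKGROUND = "background"


# ---------------------------------------------------------------------------
# read container and parsing


@dataclass
class ReadSet:
    """Paired reads with assigned genomic positions.

    Backed by a DataFrame with columns read_id, seq1, qual1, seq2, qual2,
    chrom, pos; the UMI is the first 10 cycles of read 2.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def umis(self) -> pd.Series:
        return self.df["seq2"].str.slice(0, UMI_LENGTH)

    @property
    def umi_quals(self) -> pd.Series:
        return self.df["qual2"].str.slice(0, UMI_LENGTH)


def read_fastq_pair(
    fastq1: str | Path,
    fastq2: str | Path,
    positions: pd.DataFrame | str | Path | None = None,
) -> ReadSet:
    """Parse a read pair into a :class:`ReadSet`.

    ``positions`` is a truth table (read_id, chrom, pos) or a path to one;
    reads without a position get chrom=None.  Reads present in only one mate
    file are kept with the other mate missing, so QC can count them.
    """
    r1 = {}
    with pysam.FastxFile(str(fastq1)) as fh:
        for rec in fh:
            r1[rec.name] = (rec.sequence, rec.quality)
    rows = []
    seen = set()
    with pysam.FastxFile(str(fastq2)) as fh:
        for rec in fh:
            seen.add(rec.name)
            s1, q1 = r1.get(rec.name, (None, None))
            rows.append((rec.name, s1, q1, rec.sequence, rec.quality))
    for name, (s1, q1) in r1.items():
        if name not in seen:
            rows.append((name, s1, q1, None, None))
    df = pd.DataFrame(rows, columns=["read_id", "seq1", "qual1", "seq2", "qual2"])
    df["chrom"] = None
    df["pos"] = -1
    if positions is not None:
        if not isinstance(positions, pd.DataFrame):
            positions = pd.read_csv(positions, sep="\t")
        pos = positions.drop_duplicates("read_id").set_index("read_id")
        hit = df["read_id"].isin(pos.index)
        df.loc[hit, "chrom"] = pos.loc[df.loc[hit, "read_id"], "chrom"].to_numpy()
        df.loc[hit, "pos"] = pos.loc[df.loc[hit, "read_id"], "pos"].to_numpy()
    return ReadSet(df)


def readset_from_sam(path: str | Path) -> ReadSet:
    """Build a ReadSet from a name-grouped SAM/BAM with ``RX``/``UMI`` tags.

    The 5'-most aligned base of read 1 provides the assigned position; the
    UMI is taken from the RX tag and prepended to a synthetic read-2 field so
    the downstream contract (UMI = first 10 cycles of R2) holds.
    """
    mates: dict[str, dict] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            rec = mates.setdefault(aln.query_name, {})
            umi = None
            if aln.has_tag("RX"):
                umi = aln.get_tag("RX")
            elif aln.has_tag("UMI"):
                umi = aln.get_tag("UMI")
            if umi is not None:
                rec["umi"] = umi
            which = "r2" if aln.is_read2 else "r1"
            rec[which] = (
                aln.query_sequence,
                "".join(chr(q + 33) for q in (aln.query_qualities or [])) or None,
                aln.reference_name if not aln.is_unmapped else None,
                aln.reference_start if not aln.is_unmapped else -1,
            )
    rows = []
    for name, rec in mates.items():
        s1 = q1 = s2 = q2 = None
        chrom, pos = None, -1
        if "r1" in rec:
            s1, q1, chrom, pos = rec["r1"]
        if "r2" in rec:
            s2, q2 = rec["r2"][0], rec["r2"][1]
        umi = rec.get("umi")
        if umi is not None and (s2 is None or not s2.startswith(umi)):
            s2 = umi + (s2 or "")
            q2 = "I" * len(umi) + (q2 or "")
        rows.append((name, s1, q1, s2, q2, chrom, pos))
    return ReadSet(
        pd.DataFrame(
            rows, columns=["read_id", "seq1", "qual1", "seq2", "qual2", "chrom", "pos"]
        )
    )


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    total: int = 0
    kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n


def qc_filter_reads(reads: ReadSet, min_length: int = 20) -> tuple[ReadSet, QCReport]:
    """Drop mate-less reads, reads with a mate shorter than 20 bp, and reads
    whose UMI contains an N or a Q0 base."""
    df = reads.df
    report = QCReport(total=len(df))
    single = df["seq1"].isna() | df["seq2"].isna()
    len1 = df["seq1"].str.len().fillna(0)
    len2 = df["seq2"].str.len().fillna(0)
    short = ~single & ((len1 < min_length) | (len2 < min_length))
    no_umi = ~single & ~short & (len2 < UMI_LENGTH)
    umi = df["seq2"].str.slice(0, UMI_LENGTH)
    umi_q = df["qual2"].str.slice(0, UMI_LENGTH)
    has_n = ~single & ~short & ~no_umi & umi.str.contains("N", na=False)
    # Q0 encodes as '!' in phred+33
    has_q0 = ~single & ~short & ~no_umi & ~has_n & umi_q.str.contains("!", regex=False, na=False)
    bad = single | short | no_umi | has_n | has_q0
    report.drop("single_end", int(single.sum()))
    report.drop("short", int(short.sum()))
    report.drop("no_umi", int(no_umi.sum()))
    report.drop("umi_N", int(has_n.sum()))
    report.drop("umi_q0", int(has_q0.sum()))
    kept = ReadSet(df.loc[~bad].reset_index(drop=True))
    report.kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# site assignment


def assign_reads_to_sites(reads: ReadSet, sites: SacIISiteTable) -> ReadSet:
    """Attach a ``site_id`` column: a read belongs to site s iff its 5'-most
    base equals s.motif_start + 2; everything else pools as background."""
    df = reads.df.copy()
    known = {s.chrom for s in sites}
    lut = {(s.chrom, s.cut_position): s.site_id for s in sites}
    site_ids = []
    unknown_contigs = set()
    for chrom, pos in zip(df["chrom"], df["pos"]):
        if chrom is None or (isinstance(chrom, float) and np.isnan(chrom)):
            site_ids.append(BACKGROUND)
            continue
        if chrom not in known:
            unknown_contigs.add(chrom)
        site_ids.append(lut.get((chrom, pos), BACKGROUND))
    if unknown_contigs:
        warnings.warn(
            f"reads on contigs absent from the site table pooled as background: "
            f"{sorted(unknown_contigs)}"
        )
    df["site_id"] = site_ids
    return ReadSet(df)


# ---------------------------------------------------------------------------
# UMI deduplication (directional clustering)


def _encode_umis(umis: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(umis).encode(), dtype=np.uint8).reshape(
        len(umis), -1
    )


def directional_cluster(umis: Sequence[str], counts: Sequence[int]) -> list[list[int]]:
    """Directional adjacency clustering of UMIs within one position group.

    u adopts v when Hamming(u, v) <= 1 and count(u) >= 2*count(v) - 1;
    clusters grow by BFS from UMIs in descending count order.  Returns index
    lists, each headed by its highest-count representative.
    """
    k = len(umis)
    if k == 0:
        return []
    if k == 1:
        return [[0]]
    counts = np.asarray(counts)
    enc = _encode_umis(umis)
    ham = (enc[:, None, :] != enc[None, :, :]).sum(axis=2)
    order = sorted(range(k), key=lambda i: (-counts[i], umis[i]))
    visited = np.zeros(k, dtype=bool)
    clusters = []
    for seed in order:
        if visited[seed]:
            continue
        comp = [seed]
        visited[seed] = True
        stack = [seed]
        while stack:
            u = stack.pop()
            nbrs = np.where((ham[u] <= 1) & ~visited & (counts[u] >= 2 * counts - 1))[0]
            for v in nbrs:
                visited[v] = True
                comp.append(int(v))
                stack.append(int(v))
        clusters.append(comp)
    return clusters


def deduplicate_umis(assigned: ReadSet) -> tuple[pd.DataFrame, float]:
    """Collapse PCR duplicates within each site / background-position group.

    Returns (molecule table, dedup_ratio).  The molecule table has one row
    per UMI cluster: group (site_id or background position key), umi of the
    representative, n_reads, and the representative read-1 sequence (from
    the highest-count UMI's first read).
    """
    df = assigned.df
    if len(df) == 0:
        return (
            pd.DataFrame(columns=["site_id", "group", "umi", "n_reads", "rep_seq1"]),
            1.0,
        )
    umis = df["seq2"].str.slice(0, UMI_LENGTH).to_numpy()
    site_arr = df["site_id"].to_numpy()
    group_key = np.where(
        site_arr != BACKGROUND,
        site_arr,
        [f"{BACKGROUND}:{c}:{p}" for c, p in zip(df["chrom"], df["pos"])],
    )
    seq1 = df["seq1"].to_numpy()
    # one global pass: unique (group, umi) pairs with counts and first read
    combo = np.char.add(np.char.add(group_key.astype(str), "\x00"), umis.astype(str))
    _, first_idx, counts = np.unique(combo, return_index=True, return_counts=True)
    pair_group = group_key[first_idx]
    pair_site = site_arr[first_idx]
    pair_umi = umis[first_idx]
    pair_seq = seq1[first_idx]
    order = np.argsort(pair_group, kind="stable")
    rows = []
    start = 0
    while start < len(order):
        stop = start
        grp = pair_group[order[start]]
        while stop < len(order) and pair_group[order[stop]] == grp:
            stop += 1
        sel = order[start:stop]
        u_list = list(pair_umi[sel])
        n_arr = counts[sel]
        for comp in directional_cluster(u_list, n_arr):
            rep = comp[0]
            rows.append(
                (
                    pair_site[sel[rep]],
                    grp,
                    u_list[rep],
                    int(n_arr[comp].sum()),
                    pair_seq[sel[rep]],
                )
            )
        start = stop
    molecules = pd.DataFrame(
        rows, columns=["site_id", "group", "umi", "n_reads", "rep_seq1"]
    )
    dedup_ratio = len(molecules) / len(df)
    return molecules, dedup_ratio


# ---------------------------------------------------------------------------
# on-target classification


def classify_on_target(seq: str | None) -> bool:
    """A molecule is on-target iff its genome-facing read begins "GCGG"."""
    if seq is None or len(seq) < 4:
        return False
    return seq[:4] == ON_TARGET_PREFIX


def on_target_ratio(molecules: pd.DataFrame) -> float:
    """On-target molecules / total deduplicated molecules."""
    if len(molecules) == 0:
        return float("nan")
    flags = molecules["rep_seq1"].map(classify_on_target)
    return float(flags.mean())


# ---------------------------------------------------------------------------
# normalization


def trimmed_mean_normalize(row: np.ndarray | pd.Series) -> tuple[float, np.ndarray]:
    """Trimmed-mean normalization of one sample's site-depth vector.

    Sorts the row and excludes floor(0.05*n) values from each tail (10% of
    outliers in total, symmetric), averages the remainder, and divides the
    raw row by that trimmed mean.
    """
    values = np.asarray(row, dtype=float)
    n = values.size
    if n == 0 or not np.any(values):
        raise ValueError("degenerate sample: all-zero depth row")
    if n < 10:
        warnings.warn(f"row of length {n} < 10: using plain mean")
        tm = float(values.mean())
    else:
        k = int(np.floor(0.05 * n))
        core = np.sort(values)[k : n - k] if k else np.sort(values)
        tm = float(core.mean())
    if tm == 0:
        raise ValueError("degenerate sample: trimmed mean is zero")
    return tm, values / tm


# ---------------------------------------------------------------------------
# depth matrix


@dataclass
class DepthMatrix:
    """Samples x sites deduplicated depths plus normalized values and QC."""

    raw: pd.DataFrame
    trimmed_means: pd.Series
    normalized: pd.DataFrame
    qc: pd.DataFrame | None = None

    @classmethod
    def from_raw(cls, raw: pd.DataFrame, qc: pd.DataFrame | None = None) -> "DepthMatrix":
        tms, rows = {}, {}
        for sid, row in raw.iterrows():
            tm, norm = trimmed_mean_normalize(row.to_numpy())
            tms[sid] = tm
            rows[sid] = norm
        trimmed = pd.Series(tms, name="trimmed_mean")
        normalized = pd.DataFrame.from_dict(rows, orient="index")
        normalized.columns = raw.columns
        normalized = normalized.loc[raw.index]
        return cls(raw, trimmed, normalized, qc)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.raw.columns)

    def coverage_fraction(self) -> pd.Series:
        """Per-sample fraction of sites with depth >= 1."""
        return (self.raw >= 1).mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.raw.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DepthMatrix":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_raw(raw)


def build_depth_matrix(
    sample_depths: Mapping[str, pd.Series],
    sites: SacIISiteTable,
    qc: pd.DataFrame | None = None,
) -> DepthMatrix:
    """Assemble per-sample site-depth vectors into a DepthMatrix.

    Every sample must cover exactly the site universe of ``sites``; the
    column order follows the site table.
    """
    universe = sites.site_ids
    uset = set(universe)
    rows = {}
    for sid, series in sample_depths.items():
        if set(series.index) != uset:
            raise ValueError(f"sample {sid!r} has an inconsistent site set")
        rows[sid] = series.reindex(universe)
    raw = pd.DataFrame.from_dict(rows, orient="index")
    raw.index.name = "sample_id"
    return DepthMatrix.from_raw(raw, qc)


# ---------------------------------------------------------------------------
# one-sample pipeline


def preprocess_fastq_sample(
    fastq1: str | Path,
    fastq2: str | Path,
    positions: pd.DataFrame | str | Path,
    sites: SacIISiteTable,
) -> tuple[pd.Series, dict]:
    """FASTQ pair + positions -> per-site molecule counts and QC metrics."""
    reads = read_fastq_pair(fastq1, fastq2, positions)
    kept, report = qc_filter_reads(reads)
    assigned = assign_reads_to_sites(kept, sites)
    molecules, dedup_ratio = deduplicate_umis(assigned)
    on_tgt = on_target_ratio(molecules)
    counts = (
        molecules.loc[molecules["site_id"] != BACKGROUND]
        .groupby("site_id")
        .size()
        .reindex(sites.site_ids, fill_value=0)
    )
    qc = {
        "reads_total": report.total,
        "reads_kept": report.kept,
        "dropped": report.dropped,
        "molecules": int(len(molecules)),
        "dedup_ratio": dedup_ratio,
        "on_target_ratio": on_tgt,
    }
    return counts, qc
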