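"""Synthetic cfDNA MRE-Seq cohorts.

The generative model mirrors what the assay measures.  Each class (healthy
control, colorectal cancer, lung cancer) has a per-site methylation
probability; cancer classes show global hypomethylation (a small genome-wide
downward shift of methylation) plus a class-specific set of strongly
demethylated sites, which is what makes cancer-signal-origin classification
possible.  A patient's plasma is a mixture: tumor fraction ``tf`` of
tumor-derived cfDNA in a background of normal cfDNA.  SacII cuts only
unmethylated sites, so the per-site cut probability of a sample is

    p_cut(site) = (1 - tf) * (1 - m[control, site]) + tf * (1 - m[class, site])

and deduplicated depth at a site is Poisson with mean ``D * p_cut`` plus a
Poisson off-target background.  The read-level path additionally emulates
UMI tagging, PCR duplication, 200-550 bp size-selected fragments, 100 bp
paired-end reads (UMI in the first 10 cycles of read 2) and substitution
errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sites import CUT_OFFSET, GenomeSequence, SacIISiteTable, SACII_MOTIF

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

CONTROL = "control"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CancerClassConfig:
    """Generative parameters of one cancer class.

    delta: global hypomethylation shift subtracted from every site's control
        methylation (clipped at 0).
    n_demethylated: number of class-specific strongly demethylated sites.
    demeth_level: methylation probability assigned to those sites.
    """

    delta: float = 0.1
    n_demethylated: int | None = None  # default: 5% of sites
    demeth_level: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0,1], got {self.delta}")
        if not 0.0 <= self.demeth_level <= 1.0:
            raise ValueError(f"demeth_level must be in [0,1], got {self.demeth_level}")


@dataclass(frozen=True)
class LibraryConfig:
    """Sequencing-library emulation parameters."""

    mean_site_depth: float = 30.0
    off_target_rate: float = 0.1
    umi_length: int = 10
    pcr_duplication_mean: float = 2.0
    seq_error_rate: float = 0.001
    fragment_min: int = 200
    fragment_max: int = 550
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.fragment_min >= self.fragment_max:
            raise ValueError("fragment_min must be < fragment_max")
        if not 0 <= self.off_target_rate < 1:
            raise ValueError("off_target_rate must be in [0,1)")
        if self.pcr_duplication_mean < 1:
            raise ValueError("pcr_duplication_mean must be >= 1")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0,1)")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    truth_class: str
    tumor_fraction: float = 0.0
    stage: str | None = None
    subtype: str | None = None
    age: float = 60.0
    sex: str = "F"
    batch_id: str = "b0"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0,1]")
        if self.truth_class == CONTROL and self.tumor_fraction != 0.0:
            raise ValueError("controls must have tumor_fraction 0")
        if (self.stage is not None) != (self.truth_class != CONTROL):
            raise ValueError("stage present iff cancer")


# ---------------------------------------------------------------------------
# methylation atlas


@dataclass
class MethylationAtlas:
    """Per-class, per-site methylation probabilities."""

    classes: list[str]
    m: np.ndarray  # (n_classes, n_sites) in [0,1]
    demethylated: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 2 or self.m.shape[0] != len(self.classes):
            raise ValueError("m must be (n_classes, n_sites)")
        if np.any(self.m < 0) or np.any(self.m > 1):
            raise ValueError("methylation probabilities must be in [0,1]")
        if CONTROL not in self.classes:
            raise ValueError(f"atlas must contain a {CONTROL!r} class")
        ctrl = self.row(CONTROL)
        for c in self.cancer_classes:
            if self.row(c).mean() > ctrl.mean() + 1e-12:
                raise ValueError(f"cancer class {c!r} is not hypomethylated vs control")
        cancer = self.cancer_classes
        for i, a in enumerate(cancer):
            for b in cancer[i + 1 :]:
                sa, sb = self.demethylated.get(a), self.demethylated.get(b)
                if sa is not None and sb is not None and sa.size and np.array_equal(
                    np.sort(sa), np.sort(sb)
                ):
                    raise ValueError(
                        f"classes {a!r} and {b!r} share an identical demethylated set"
                    )

    @property
    def n_sites(self) -> int:
        return self.m.shape[1]

    @property
    def cancer_classes(self) -> list[str]:
        return [c for c in self.classes if c != CONTROL]

    def row(self, cls: str) -> np.ndarray:
        try:
            return self.m[self.classes.index(cls)]
        except ValueError:
            raise KeyError(f"class {cls!r} not in atlas; classes: {self.classes}")


def build_methylation_atlas(
    n_sites: int,
    class_config: Mapping[str, CancerClassConfig] | None = None,
    seed: int = 0,
    control_beta: tuple[float, float] = (8.0, 2.0),
) -> MethylationAtlas:
    """Draw control methylation per site from a Beta, derive cancer classes.

    Each cancer class copies the control row, subtracts its global shift
    ``delta`` (clipped at 0), and sets its class-specific demethylated subset
    to ``demeth_level``.  Deterministic given ``seed``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if class_config is None:
        class_config = {"crc": CancerClassConfig(), "lung": CancerClassConfig()}
    for cfg in class_config.values():
        cfg.validate()
    rng = np.random.default_rng(seed)
    control = rng.beta(*control_beta, size=n_sites)
    rows = [control]
    classes = [CONTROL]
    demeth: dict[str, np.ndarray] = {}
    for name, cfg in class_config.items():
        k = cfg.n_demethylated
        if k is None:
            k = max(1, n_sites // 20)
        if k > n_sites:
            raise ValueError(f"n_demethylated {k} exceeds n_sites {n_sites}")
        row = np.clip(control - cfg.delta, 0.0, 1.0)
        idx = rng.choice(n_sites, size=k, replace=False) if k else np.array([], int)
        if k:
            row = row.copy()
            row[idx] = np.minimum(row[idx], cfg.demeth_level)
        classes.append(name)
        rows.append(row)
        demeth[name] = np.sort(idx)
    return MethylationAtlas(classes, np.vstack(rows), demeth)


# ---------------------------------------------------------------------------
# depth-level simulation


def _cut_probabilities(atlas: MethylationAtlas, meta: SampleMetadata) -> np.ndarray:
    m_ctrl = atlas.row(CONTROL)
    m_cls = atlas.row(meta.truth_class)
    tf = meta.tumor_fraction
    return (1.0 - tf) * (1.0 - m_ctrl) + tf * (1.0 - m_cls)


def _on_target_counts(
    atlas: MethylationAtlas, meta: SampleMetadata, lib: LibraryConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    return rng.poisson(lib.mean_site_depth * _cut_probabilities(atlas, meta))


def simulate_sample_depths(
    atlas: MethylationAtlas,
    meta: SampleMetadata,
    lib: LibraryConfig,
    seed: int,
) -> np.ndarray:
    """Deduplicated molecule counts per site for one sample.

    On-target component Poisson(D * p_cut) plus off-target background
    Poisson(D * off_target_rate) at each site.  The on-target draw shares its
    random stream with :func:`simulate_reads`, so with ``off_target_rate=0``
    the direct depths equal the read-path molecule counts for the same seed.
    """
    rng = np.random.default_rng(seed)
    depths = _on_target_counts(atlas, meta, lib, rng)
    if lib.off_target_rate > 0:
        depths = depths + rng.poisson(
            lib.mean_site_depth * lib.off_target_rate, size=atlas.n_sites
        )
    return depths


# ---------------------------------------------------------------------------
# read-level simulation


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _rows_to_strings(arr: np.ndarray) -> list[str]:
    return arr.tobytes().decode().split("\n") if arr.size else []


def _apply_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return reads
    mask = rng.random(reads.shape) < rate
    subs = _BASES[rng.integers(0, 4, size=reads.shape)]
    return np.where(mask, subs, reads)


@dataclass
class SimulatedLibrary:
    sample_id: str
    fastq1: Path
    fastq2: Path
    truth: Path
    n_molecules: int
    n_reads: int
    n_resampled_fragments: int


def simulate_reads(
    atlas: MethylationAtlas,
    meta: SampleMetadata,
    genome: GenomeSequence,
    sites: SacIISiteTable,
    lib: LibraryConfig,
    seed: int,
    out_dir: str | Path,
) -> SimulatedLibrary:
    """Emit a paired FASTQ library plus a read-level truth table.

    Read 1 is the genome-facing read starting at the SacII cut terminus
    (``motif_start + 2``), so error-free on-target reads begin "GCGG".
    Read 2 carries the 10 bp UMI in its first cycles followed by the reverse
    complement of the fragment 3' end.  Each molecule is emitted ``1 + k``
    times, ``k ~ Poisson(pcr_duplication_mean - 1)``, as PCR duplicates
    sharing the UMI.  Off-target molecules start at uniform random positions.
    """
    if len(sites) != atlas.n_sites:
        raise ValueError("site table and atlas disagree on the number of sites")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    counts = _on_target_counts(atlas, meta, lib, rng)

    chrom_arrs = {n: _seq_to_array(genome[n]) for n in genome.names}

    # molecule start positions: on-target at each cut terminus, then background
    chroms: list[str] = []
    starts: list[int] = []
    origins: list[str] = []
    site_list = list(sites)
    for s, c in zip(site_list, counts):
        if c:
            chroms.extend([s.chrom] * int(c))
            starts.extend([s.cut_position] * int(c))
            origins.extend([s.site_id] * int(c))
    n_off = rng.poisson(atlas.n_sites * lib.mean_site_depth * lib.off_target_rate)
    if n_off:
        names = genome.names
        lens = np.array([len(chrom_arrs[n]) for n in names])
        picks = rng.integers(0, len(names), size=n_off)
        for p in picks:
            max_start = max(1, lens[p] - lib.fragment_min)
            chroms.append(names[p])
            starts.append(int(rng.integers(0, max_start)))
            origins.append("background")

    n_mol = len(starts)
    starts_a = np.asarray(starts, dtype=np.int64)
    lengths = rng.integers(lib.fragment_min, lib.fragment_max + 1, size=n_mol)
    # resample fragment lengths that run past the contig end
    n_resampled = 0
    clens = np.array([len(chrom_arrs[c]) for c in chroms], dtype=np.int64)
    for _ in range(100):
        over = starts_a + lengths > clens
        if not over.any():
            break
        n_resampled += int(over.sum())
        lengths[over] = rng.integers(lib.fragment_min, lib.fragment_max + 1, size=int(over.sum()))
        short = over & (starts_a + lib.fragment_min > clens)
        if short.any():
            # even the minimum fragment does not fit; clamp to contig end
            lengths[short] = clens[short] - starts_a[short]
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} fragment lengths extending past contig end")

    umis = _BASES[rng.integers(0, 4, size=(n_mol, lib.umi_length))]
    dup_extra = rng.poisson(lib.pcr_duplication_mean - 1.0, size=n_mol)
    copies = 1 + dup_extra
    n_reads = int(copies.sum())

    mol_of_read = np.repeat(np.arange(n_mol), copies)
    r1_len = lib.read_length
    r2_tail = lib.read_length - lib.umi_length

    # gather per-molecule R1 / R2 template sequences, then expand to reads
    r1_tmpl = np.full((n_mol, r1_len), ord("N"), dtype=np.uint8)
    r2_tmpl = np.full((n_mol, lib.read_length), ord("N"), dtype=np.uint8)
    r2_tmpl[:, : lib.umi_length] = umis
    for i in range(n_mol):
        arr = chrom_arrs[chroms[i]]
        frag = arr[starts_a[i] : starts_a[i] + lengths[i]]
        k1 = min(r1_len, frag.size)
        r1_tmpl[i, :k1] = frag[:k1]
        k2 = min(r2_tail, frag.size)
        r2_tmpl[i, lib.umi_length : lib.umi_length + k2] = _COMP[frag[::-1][:k2]]

    r1 = _apply_errors(r1_tmpl[mol_of_read], lib.seq_error_rate, rng)
    r2 = _apply_errors(r2_tmpl[mol_of_read], lib.seq_error_rate, rng)

    dup_rank = np.concatenate([np.arange(c) for c in copies]) if n_mol else np.array([], int)
    read_ids = [
        f"{meta.sample_id}:m{m}:d{d}" for m, d in zip(mol_of_read, dup_rank)
    ]
    umi_strings = ["".join(map(chr, u)) for u in umis]

    fq1 = out_dir / f"{meta.sample_id}_R1.fastq"
    fq2 = out_dir / f"{meta.sample_id}_R2.fastq"
    truth = out_dir / f"{meta.sample_id}_truth.tsv"
    qual1 = "I" * r1_len
    qual2 = "I" * lib.read_length
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for j, rid in enumerate(read_ids):
            m = mol_of_read[j]
            tag = f"UMI:Z:{umi_strings[m]}"
            s1 = r1[j].tobytes().decode()
            s2 = r2[j].tobytes().decode()
            f1.write(f"@{rid} {tag}\n{s1}\n+\n{qual1}\n")
            f2.write(f"@{rid} {tag}\n{s2}\n+\n{qual2}\n")
    truth_df = pd.DataFrame(
        {
            "read_id": read_ids,
            "chrom": [chroms[m] for m in mol_of_read],
            "pos": starts_a[mol_of_read],
            "origin": [origins[m] for m in mol_of_read],
            "molecule_id": mol_of_read,
        }
    )
    truth_df.to_csv(truth, sep="\t", index=False)
    return SimulatedLibrary(meta.sample_id, fq1, fq2, truth, n_mol, n_reads, n_resampled)


# ---------------------------------------------------------------------------
# cohorts


#: Table-1-style stage composition of the two cancer cohorts
DEFAULT_STAGE_PROBS = {
    "crc": {"I": 17 / 96, "II": 21 / 96, "III": 46 / 96, "IV": 12 / 96},
    "lung": {"I": 32 / 95, "II": 9 / 95, "III": 23 / 95, "IV": 31 / 95},
}
#: assumed stage -> tumor-fraction window (the detectability driver)
DEFAULT_TF_RANGES = {
    "I": (0.05, 0.15),
    "II": (0.10, 0.25),
    "III": (0.20, 0.40),
    "IV": (0.30, 0.60),
}
DEFAULT_SUBTYPES = {
    "crc": ({"left": 0.51, "right": 0.26, "rectum": 0.23}),
    "lung": ({"LUAD": 0.642, "LUSC": 0.211, "SCLC": 0.095, "other": 0.052}),
}
DEFAULT_FEMALE_FRACTION = {CONTROL: 0.675, "crc": 0.406, "lung": 0.326}


@dataclass(frozen=True)
class CohortPlan:
    """Per-class sample counts plus covariate distributions."""

    counts: Mapping[str, int] = field(
        default_factory=lambda: {CONTROL: 126, "crc": 96, "lung": 95}
    )
    stage_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_STAGE_PROBS
    )
    tf_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_TF_RANGES
    )
    subtypes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_SUBTYPES
    )
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_FEMALE_FRACTION
    )
    n_batches: int = 22

    def validate(self) -> None:
        if not self.counts or sum(self.counts.values()) == 0:
            raise ValueError("empty cohort plan")


def plan_metadata(plan: CohortPlan, seed: int) -> list[SampleMetadata]:
    """Draw the metadata table (stages, tumor fractions, covariates)."""
    plan.validate()
    rng = np.random.default_rng(seed)
    out: list[SampleMetadata] = []
    i = 0
    for cls, n in plan.counts.items():
        for _ in range(n):
            sid = f"S{i:04d}"
            sex = "F" if rng.random() < plan.female_fraction.get(cls, 0.5) else "M"
            batch = f"b{rng.integers(0, plan.n_batches)}"
            if cls == CONTROL:
                age = float(np.clip(rng.normal(62, 8), 30, 90))
                out.append(SampleMetadata(sid, cls, 0.0, None, None, age, sex, batch))
            else:
                stages = plan.stage_probs.get(cls, {"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.25})
                names = list(stages)
                stage = names[rng.choice(len(names), p=np.array(list(stages.values())))]
                lo, hi = plan.tf_ranges[stage]
                tf = float(rng.uniform(lo, hi))
                subs = plan.subtypes.get(cls)
                subtype = None
                if subs:
                    snames = list(subs)
                    subtype = snames[rng.choice(len(snames), p=np.array(list(subs.values())))]
                age = float(np.clip(rng.normal(66, 9), 30, 90))
                out.append(SampleMetadata(sid, cls, tf, stage, subtype, age, sex, batch))
            i += 1
    return out


def metadata_frame(metas: Sequence[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "truth_class": [m.truth_class for m in metas],
            "stage": [m.stage for m in metas],
            "subtype": [m.subtype for m in metas],
            "tumor_fraction": [m.tumor_fraction for m in metas],
            "age": [m.age for m in metas],
            "sex": [m.sex for m in metas],
            "batch_id": [m.batch_id for m in metas],
        }
    ).set_index("sample_id")


def simulate_cohort(
    atlas: MethylationAtlas,
    plan: CohortPlan,
    lib: LibraryConfig,
    seed: int,
    site_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direct-depth cohort: (raw depth DataFrame samples x sites, metadata)."""
    metas = plan_metadata(plan, seed)
    ss = np.random.SeedSequence(seed)
    sample_seeds = ss.generate_state(len(metas) + 1)[1:] % (2**31)
    rows = [
        simulate_sample_depths(atlas, m, lib, int(s))
        for m, s in zip(metas, sample_seeds)
    ]
    cols = list(site_ids) if site_ids is not None else [f"site{j}" for j in range(atlas.n_sites)]
    depth = pd.DataFrame(
        np.vstack(rows), index=[m.sample_id for m in metas], columns=cols
    )
    depth.index.name = "sample_id"
    return depth, metadata_frame(metas)


# ---------------------------------------------------------------------------
# synthetic reference genomes


def planted_sites_genome(
    n_sites: int,
    seed: int,
    spacing: int = 700,
    chrom: str = "chrS",
    tail: int = 600,
) -> GenomeSequence:
    """Random genome with exactly ``n_sites`` SacII sites at regular spacing.

    Accidental CCGCGG occurrences in the random background are disrupted by a
    single-base substitution, so site enumeration returns exactly the planted
    set; the tail leaves room for a full-length fragment after the last site.
    """
    rng = np.random.default_rng(seed)
    length = n_sites * spacing + tail
    arr = _BASES[rng.integers(0, 4, size=length)]
    motif = _seq_to_array(SACII_MOTIF)
    planted = np.arange(n_sites) * spacing
    for p in planted:
        arr[p : p + 6] = motif
    planted_set = set(planted.tolist())
    seq = arr.tobytes().decode()
    while True:
        extras = []
        i = seq.find(SACII_MOTIF)
        while i != -1:
            if i not in planted_set:
                extras.append(i)
            i = seq.find(SACII_MOTIF, i + 1)
        if not extras:
            break
        for e in extras:
            # mutate a base of the stray motif that lies outside every planted site
            for o in range(6):
                p_near = ((e + o) // spacing) * spacing
                if not (p_near <= e + o < p_near + 6 and p_near in planted_set):
                    break
            old = arr[e + o]
            choices = _BASES[_BASES != old]
            arr[e + o] = choices[rng.integers(0, len(choices))]
        seq = arr.tobytes().decode()
    return GenomeSequence({chrom: seq})
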