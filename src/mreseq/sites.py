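"""SacII recognition-site enumeration on a reference genome.

SacII recognizes the palindromic hexamer CCGCGG and is blocked by CpG
methylation within the site, which is what makes read depth at each site a
readout of its unmethylated fraction.  This module builds the marker
universe: every CCGCGG occurrence in the reference, optionally restricted to
autosomes (sex-chromosome markers are excluded from modelling to avoid
sex-linked confounding).

Coordinates are 0-based half-open internally and in the BED output.  The
simulated/observed read 5' terminus sits at ``motif_start + CUT_OFFSET`` so
that on-target reads begin with "GCGG".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

SACII_MOTIF = "CCGCGG"
#: read 5' terminus relative to motif start; on-target reads begin "GCGG"
CUT_OFFSET = 2

_ALLOWED = set("ACGTN")
_AUTOSOME_RE = re.compile(r"^(chr)?([0-9]+)$")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the offending line."""


@dataclass
class GenomeSequence:
    """Upper-cased name -> sequence map over the alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FastaParseError(f"sequence {name!r} is empty")
            bad = set(seq) - _ALLOWED
            if bad:
                raise FastaParseError(
                    f"sequence {name!r} contains characters outside A/C/G/T/N: "
                    f"{sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sequences.items()}


@dataclass(frozen=True)
class SacIISite:
    chrom: str
    motif_start: int

    @property
    def cut_position(self) -> int:
        return self.motif_start + CUT_OFFSET

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.motif_start}"


@dataclass
class SacIISiteTable:
    """Ordered catalogue of SacII sites; the marker universe."""

    sites: list[SacIISite]
    autosomes_only: bool = False
    _by_cut: dict[tuple[str, int], SacIISite] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site coordinates in table")
        self._by_cut = {(s.chrom, s.cut_position): s for s in self.sites}

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SacIISite]:
        return iter(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def site_at_cut(self, chrom: str, pos: int) -> SacIISite | None:
        """Site whose expected read 5' terminus is (chrom, pos), if any."""
        return self._by_cut.get((chrom, pos))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "motif_start": [s.motif_start for s in self.sites],
                "site_id": self.site_ids,
            }
        )


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file, case-folded to upper case.

    Raises :class:`FastaParseError` on an empty file or content before the
    first header.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if not first:
            raise FastaParseError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}: line 1 does not start with a FASTA header ('>')"
            )
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaParseError(f"{path}: duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return GenomeSequence(records)


def default_autosome_names(genome: GenomeSequence) -> list[str]:
    """Names like 'chr1'..'chr22' or '1'..'22' present in the genome."""
    out = []
    for name in genome.names:
        m = _AUTOSOME_RE.match(name)
        if m and 1 <= int(m.group(2)) <= 22:
            out.append(name)
    return out


def enumerate_sacii_sites(
    genome: GenomeSequence,
    autosomes_only: bool = False,
    autosome_names: Sequence[str] | None = None,
) -> SacIISiteTable:
    """Every CCGCGG occurrence, sorted by (chrom, start).

    The motif is its own reverse complement, so a single forward scan finds
    each physical site exactly once; CCGCGG cannot overlap itself, so sites
    are overlap-free by construction.
    """
    if not genome.sequences:
        warnings.warn("empty genome: returning empty site table")
        return SacIISiteTable([], autosomes_only=autosomes_only)
    if autosomes_only:
        names = list(autosome_names) if autosome_names is not None else default_autosome_names(genome)
        missing = [n for n in names if n not in genome]
        if missing:
            raise KeyError(f"autosome names not in genome: {missing}")
    else:
        names = genome.names
    sites: list[SacIISite] = []
    for name in sorted(names):
        seq = genome[name]
        i = seq.find(SACII_MOTIF)
        while i != -1:
            sites.append(SacIISite(name, i))
            i = seq.find(SACII_MOTIF, i + 1)
    return SacIISiteTable(sites, autosomes_only=autosomes_only)


def write_sites_bed(table: SacIISiteTable, path: str | Path) -> None:
    """BED6: 0-based half-open [motif_start, motif_start+6), name=site_id."""
    if len(table) == 0:
        warnings.warn("writing empty site table")
    with open(path, "w") as fh:
        for s in table:
            fh.write(f"{s.chrom}\t{s.motif_start}\t{s.motif_start + 6}\t{s.site_id}\t0\t+\n")


def read_sites_bed(path: str | Path) -> SacIISiteTable:
    """Inverse of :func:`write_sites_bed`."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end = line.split("\t")[:3]
            sites.append(SacIISite(chrom, int(start)))
    return SacIISiteTable(sites)
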