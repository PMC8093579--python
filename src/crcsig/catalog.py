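"""Somatic mutation parsing and the samples x 96 mutation catalog.

Reads MAF files in the GDC dialect (tab-separated, ``#`` comment lines,
``Tumor_Sample_Barcode`` etc.), resolves the trinucleotide context of
each SNV against a reference FASTA, and accumulates per-sample counts
over the 96 substitution channels.  Indels and multi-nucleotide variants
are kept as records (they count toward total mutation burden) but never
enter the 96-channel catalog.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .channels import (
    AmbiguousBaseError,
    CHANNELS,
    N_CHANNELS,
    classify_substitution,
)

# GDC MAF column names; each required concept maps to accepted aliases
# (case-insensitive).
_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "chrom": ("chromosome", "chrom", "chr"),
    "pos": ("start_position", "start_pos", "position", "start"),
    "ref": ("reference_allele", "ref_allele", "ref"),
    "alt": ("tumor_seq_allele2", "alt_allele", "alt", "tumor_allele"),
    "variant_type": ("variant_type",),
    "sample": ("tumor_sample_barcode", "sample_id", "sample"),
}


class MafFormatError(ValueError):
    """Raised when a MAF file lacks a required column."""


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_type: str  # "SNV" or "other"

    @property
    def is_snv(self) -> bool:
        return self.variant_type == "SNV"


class RejectLog:
    """Counts of mutations excluded from the catalog, keyed by reason."""

    def __init__(self) -> None:
        self.counts: collections.Counter[str] = collections.Counter()

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] += n

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["reason", "count"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class MutationCatalog:
    """Samples x 96 matrix of SNV counts in fixed COSMIC channel order."""

    samples: list[str]
    counts: np.ndarray  # (n_samples, 96) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), N_CHANNELS):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {N_CHANNELS} channels"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.samples, name="sample_id"),
            columns=list(CHANNELS),
        )

    def frequencies(self) -> np.ndarray:
        """Per-sample channel frequencies (rows sum to 1; zero rows stay zero)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.counts / totals, 0.0)
        return freq

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = [c for c in CHANNELS if c not in df.columns]
        if missing:
            raise ValueError(f"catalog file missing channels: {missing[:3]}...")
        return cls(list(df.index.astype(str)), df[list(CHANNELS)].to_numpy())


def _resolve_columns(header: Iterable[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in header}
    resolved = {}
    for key, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[key] = lower[alias]
                break
        else:
            raise MafFormatError(
                f"MAF is missing a required column for '{key}' "
                f"(accepted names: {', '.join(aliases)})"
            )
    return resolved


def read_maf(
    path: str | Path, reject_log: RejectLog | None = None
) -> list[MutationRecord]:
    """Parse a GDC-dialect MAF into mutation records.

    Rows whose variant type is not a single-nucleotide substitution are
    retained with ``variant_type="other"``; ``#`` comment lines are
    skipped.  Rows with an unparseable position are rejected and counted
    in *reject_log*.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    if df.empty and len(df.columns) <= 1:
        raise MafFormatError(f"{path}: no tab-separated header found")
    cols = _resolve_columns(df.columns)
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        row_d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            pos = int(str(row_d[cols["pos"]]))
        except (TypeError, ValueError):
            if reject_log is not None:
                reject_log.add("unparseable_position")
            continue
        ref = str(row_d[cols["ref"]]).upper()
        alt = str(row_d[cols["alt"]]).upper()
        vt_raw = str(row_d[cols["variant_type"]]).upper()
        is_snv = (
            vt_raw in ("SNP", "SNV")
            and len(ref) == 1
            and len(alt) == 1
            and ref != alt
        )
        records.append(
            MutationRecord(
                sample_id=str(row_d[cols["sample"]]),
                chrom=str(row_d[cols["chrom"]]),
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                variant_type="SNV" if is_snv else "other",
            )
        )
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records back out as a minimal GDC-style MAF."""
    rows = [
        {
            "Chromosome": r.chrom,
            "Start_Position": r.pos,
            "Reference_Allele": r.ref_allele,
            "Tumor_Seq_Allele2": r.alt_allele,
            "Variant_Type": "SNP" if r.is_snv else "OTHER",
            "Tumor_Sample_Barcode": r.sample_id,
        }
        for r in records
    ]
    with open(path, "w") as fh:
        fh.write("#version crcsig minimal MAF\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def _fetch(reference: Mapping[str, object], chrom: str, start0: int, end0: int) -> str:
    """Fetch reference sequence [start0, end0) 0-based; '' when out of range.

    Works with pyfaidx.Fasta, plain dict[str, str] and similar mappings.
    """
    seq = reference[chrom]
    start0 = max(start0, 0)
    return str(seq[start0:end0]).upper()


def build_catalog(
    records: Iterable[MutationRecord],
    reference: Mapping[str, object],
    samples: Iterable[str] | None = None,
    reject_log: RejectLog | None = None,
    missing_chrom: str = "fail",
) -> MutationCatalog:
    """Accumulate SNVs into the samples x 96 catalog.

    MAF positions are 1-based; flanking bases are looked up at
    [pos-1, pos+1].  Mutations whose reference allele disagrees with the
    FASTA are dropped (never repaired) and counted in *reject_log*, as
    are mutations with ambiguous (non-ACGT) context bases.

    Parameters
    ----------
    samples
        Optional explicit sample order; samples without SNVs keep an
        all-zero row.  Defaults to order of first appearance.
    missing_chrom
        ``"fail"`` (default) raises when a record's chromosome is absent
        from the reference; ``"skip"`` rejects the record instead.
    """
    if reject_log is None:
        reject_log = RejectLog()
    records = list(records)
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.sample_id, None)
        samples = list(seen)
    else:
        samples = list(samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), N_CHANNELS), dtype=np.int64)

    for r in records:
        if not r.is_snv:
            reject_log.add("non_snv")
            continue
        if r.sample_id not in sample_idx:
            reject_log.add("sample_not_listed")
            continue
        if r.chrom not in reference:
            if missing_chrom == "fail":
                raise KeyError(f"chromosome {r.chrom!r} absent from reference")
            reject_log.add("chromosome_missing")
            continue
        tri = _fetch(reference, r.chrom, r.pos - 2, r.pos + 1)
        if len(tri) != 3:
            reject_log.add("flank_out_of_range")
            continue
        five, ref_base, three = tri[0], tri[1], tri[2]
        if ref_base != r.ref_allele:
            reject_log.add("reference_mismatch")
            continue
        try:
            ch = classify_substitution(r.ref_allele, r.alt_allele, five, three)
        except AmbiguousBaseError:
            reject_log.add("ambiguous_context")
            continue
        counts[sample_idx[r.sample_id], ch.index] += 1

    return MutationCatalog(samples, counts)
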