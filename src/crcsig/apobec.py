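"""APOBEC tCw enrichment per sample.

APOBEC cytidine deaminases preferentially mutate cytosine in the tCw
motif (w in {A, T}), producing C>T and C>G substitutions.  Following the
Roberts-style enrichment analysis, each sample's fold enrichment is

    E = (n_mut_tCw / n_mut_C) / (ctx_tCw / ctx_C)

where n_mut_tCw counts APOBEC-type (C>T, C>G) mutations at tCw,
n_mut_C counts APOBEC-type mutations at any cytosine, and the background
context counts ctx_tCw / ctx_C tally tCw motifs and cytosines within a
window (default +/-20 bases) around each mutated cytosine, on both
strands (a G on the given strand is a C on the other; wGa is the reverse
complement of tCw).  Significance is a one-sided Fisher exact test on
the 2x2 table of mutated vs background counts, BH-corrected across
samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .catalog import MutationRecord, _fetch
from .channels import COMPLEMENT
from .survstats import bh_fdr

_APOBEC_ALTS = {"T", "G"}  # C>T and C>G on the pyrimidine strand
_W = {"A", "T"}


@dataclass
class ApobecResult:
    sample_id: str
    n_mut_tcw: int
    n_mut_c: int
    ctx_tcw: int
    ctx_c: int
    enrichment: float | None
    p_value: float | None
    fdr: float | None = None
    enriched: bool = False
    evaluable: bool = True


def _count_context(extended: str) -> tuple[int, int]:
    """Count (tCw motifs, cytosines) in the core of *extended*, both strands.

    *extended* carries one extra base on each side of the core window so
    every core position can be motif-evaluated with its true neighbours;
    counting cytosines over a window whose edge bases cannot be scanned
    would deflate the tCw/C background ratio and bias E upward.
    """
    ctx_c = 0
    ctx_tcw = 0
    for i in range(1, len(extended) - 1):
        a, b, c = extended[i - 1], extended[i], extended[i + 1]
        if b in ("C", "G"):
            ctx_c += 1
        if b == "C" and a == "T" and c in _W:
            ctx_tcw += 1
        # reverse strand: wGa on this strand is tCw on the other
        if b == "G" and c == "A" and a in _W:
            ctx_tcw += 1
    return ctx_tcw, ctx_c


def _is_apobec_type(ref: str, alt: str) -> bool:
    if ref == "C":
        return alt in _APOBEC_ALTS
    if ref == "G":
        return COMPLEMENT[alt] in _APOBEC_ALTS
    return False


def apobec_enrichment(
    records: Iterable[MutationRecord],
    reference: Mapping[str, object],
    flank: int = 20,
    fdr_threshold: float = 0.05,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample APOBEC tCw fold enrichment with Fisher p and BH FDR.

    Samples with no APOBEC-type cytosine mutation (or an empty tCw
    background) are flagged not evaluable rather than given E = 0.

    Returns a DataFrame indexed by sample with columns
    ``n_mut_tcw, n_mut_c, ctx_tcw, ctx_c, enrichment, p_value, fdr,
    enriched, evaluable``.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    per_sample: dict[str, ApobecResult] = {}
    order: list[str] = list(samples) if samples is not None else []
    for s in order:
        per_sample[s] = ApobecResult(s, 0, 0, 0, 0, None, None)

    for r in records:
        if r.sample_id not in per_sample:
            if samples is not None:
                continue
            order.append(r.sample_id)
            per_sample[r.sample_id] = ApobecResult(r.sample_id, 0, 0, 0, 0, None, None)
        res = per_sample[r.sample_id]
        if not r.is_snv or r.ref_allele not in ("C", "G"):
            continue
        if not _is_apobec_type(r.ref_allele, r.alt_allele):
            continue
        if r.chrom not in reference:
            continue
        tri = _fetch(reference, r.chrom, r.pos - 2, r.pos + 1)
        if len(tri) != 3 or tri[1] != r.ref_allele:
            continue
        res.n_mut_c += 1
        if r.ref_allele == "C":
            at_tcw = tri[0] == "T" and tri[2] in _W
        else:  # G strand: wGa
            at_tcw = tri[2] == "A" and tri[0] in _W
        if at_tcw:
            res.n_mut_tcw += 1
        # one extra base each side so edge positions of the +/-flank core
        # can be motif-scanned with their real neighbours
        window = _fetch(reference, r.chrom, r.pos - 2 - flank, r.pos + 1 + flank)
        tcw, c = _count_context(window)
        res.ctx_tcw += tcw
        res.ctx_c += c

    for res in per_sample.values():
        if res.n_mut_c == 0 or res.ctx_tcw == 0 or res.ctx_c == 0:
            res.evaluable = False
            continue
        res.enrichment = (res.n_mut_tcw / res.n_mut_c) / (res.ctx_tcw / res.ctx_c)
        table = [
            [res.n_mut_tcw, res.n_mut_c - res.n_mut_tcw],
            [res.ctx_tcw, res.ctx_c - res.ctx_tcw],
        ]
        res.p_value = float(stats.fisher_exact(table, alternative="greater")[1])

    evaluable = [s for s in order if per_sample[s].evaluable]
    if evaluable:
        fdrs = bh_fdr([per_sample[s].p_value for s in evaluable])
        for s, q in zip(evaluable, fdrs):
            per_sample[s].fdr = float(q)
            per_sample[s].enriched = q < fdr_threshold

    rows = [vars(per_sample[s]) for s in order]
    return pd.DataFrame(rows).set_index("sample_id")
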