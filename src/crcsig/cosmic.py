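"""Reference mutational-signature table handling.

A signature reference is a 96 x n_signatures table of channel
probabilities (columns sum to 1) in the fixed channel order of
:mod:`crcsig.channels`.  The packaged table
``data/cosmic_v2_synthetic.tsv`` is a SYNTHETIC stand-in for the COSMIC
v2 catalogue: 30 deterministic, mutually near-orthogonal sparse
profiles named "Signature 1" ... "Signature 30", generated by
:func:`make_synthetic_reference`.  It supports planted-recovery and
annotation tests without any download; a genuine COSMIC v2 table in the
same layout can be supplied to :func:`load_reference` instead.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS, N_CHANNELS

_PACKAGED = "cosmic_v2_synthetic.tsv"
_SEED_ROOT = 761235  # fixed: the packaged table must never change


def make_synthetic_reference(n_signatures: int = 30) -> pd.DataFrame:
    """Deterministically generate the synthetic signature reference.

    Each profile is a sparse Dirichlet draw (concentration 0.1) from its
    own fixed seed stream, so profiles are spiky — a few dominant
    channels each — and pairwise cosine similarities are low, which is
    what makes annotation by nearest-cosine unambiguous in tests.
    """
    cols = {}
    for s in range(1, n_signatures + 1):
        rng = np.random.default_rng(np.random.SeedSequence([_SEED_ROOT, s]))
        prof = rng.dirichlet(np.full(N_CHANNELS, 0.1))
        cols[f"Signature {s}"] = prof / prof.sum()
    df = pd.DataFrame(cols, index=pd.Index(CHANNELS, name="channel"))
    return df


def load_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Load a signature reference table (channels x signatures).

    With no *path*, returns the packaged synthetic table.  The table is
    validated (96 rows, known channel labels, columns summing to 1) and
    reordered to the canonical channel order.
    """
    if path is None:
        ref = importlib.resources.files("crcsig.data").joinpath(_PACKAGED)
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != N_CHANNELS:
        raise ValueError(f"reference must have {N_CHANNELS} rows, got {df.shape[0]}")
    missing = [c for c in CHANNELS if c not in df.index]
    if missing:
        raise ValueError(f"reference lacks channels, e.g. {missing[:3]}")
    df = df.loc[list(CHANNELS)].astype(float)
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("reference columns must sum to 1 (+/- 1e-6)")
    return df
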