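"""Seeded synthetic-data generators with planted ground truth.

Every input the analysis stages consume can be generated here: mutation
catalogs as multinomial draws from Dirichlet-mixed planted signatures, a
toy reference genome with a matching MAF whose channel truth is known by
construction, and multi-cohort expression/survival data with a planted
prognostic gene pair, cohort-specific strictly monotone batch
distortions, exponential survival under proportional hazards, and
independent uniform censoring.  All generators are pure functions of
their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import MutationCatalog, MutationRecord, write_maf
from .channels import CHANNELS, classify_substitution
from .cosmic import load_reference
from .pairs import ExpressionCohort, pair_label

# strictly increasing transforms emulating platform/batch distortions
BATCH_TRANSFORMS = {
    "identity": lambda x: x,
    "exp": lambda x: np.exp(x / 2.0),
    "affine": lambda x: 2.0 * x + 5.0,
    "cube": lambda x: x**3,
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x / 2.0)),
    "softplus": lambda x: np.log1p(np.exp(np.clip(x, -30, 30))),
}


# ----------------------------------------------------------- mutation catalog

@dataclass
class CatalogSimSpec:
    """Conditions for a planted-signature mutation catalog."""

    n_samples: int = 200
    signatures: tuple[str, ...] = ("Signature 1", "Signature 6", "Signature 10")
    dirichlet_alpha: float = 1.0
    mutations_per_sample: float = 100.0  # Poisson mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dirichlet_alpha <= 0:
            raise ValueError("Dirichlet alpha must be > 0")
        if self.mutations_per_sample <= 0:
            raise ValueError("mutation rate must be > 0")


def simulate_catalog(
    spec: CatalogSimSpec, reference: pd.DataFrame | None = None
) -> tuple[MutationCatalog, pd.DataFrame]:
    """Draw a catalog from planted signatures; returns (catalog, truth).

    Per sample: exposure ~ Dirichlet(alpha), mutation count m ~ Poisson,
    channel counts ~ Multinomial(m, exposures @ profiles).  The truth
    table holds each sample's exposure fractions over the planted
    signatures.
    """
    if reference is None:
        reference = load_reference()
    missing = [s for s in spec.signatures if s not in reference.columns]
    if missing:
        raise ValueError(f"unknown signature names: {missing}")
    P = reference[list(spec.signatures)].to_numpy()  # 96 x k
    k = P.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    samples = [f"SIM{i:04d}" for i in range(spec.n_samples)]
    counts = np.zeros((spec.n_samples, len(CHANNELS)), dtype=np.int64)
    truth = np.zeros((spec.n_samples, k))
    for i in range(spec.n_samples):
        expo = rng.dirichlet(np.full(k, spec.dirichlet_alpha))
        truth[i] = expo
        m = rng.poisson(spec.mutations_per_sample)
        if m > 0:
            probs = P @ expo
            counts[i] = rng.multinomial(m, probs / probs.sum())
    truth_df = pd.DataFrame(truth, index=pd.Index(samples, name="sample_id"),
                            columns=list(spec.signatures))
    return MutationCatalog(samples, counts), truth_df


# ------------------------------------------------------------- cohort survival

@dataclass
class PlantedPair:
    """A gene pair whose state drives hazard and metastasis."""

    gene_a: str = "GENE_A"
    gene_b: str = "GENE_B"
    hazard_ratio: float = 2.5       # hazard of state A>B vs B>A
    metastasis_rates: tuple[float, float] = (0.40, 0.15)  # (A>B, B>A)

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")
        for r in self.metastasis_rates:
            if not 0 <= r <= 1:
                raise ValueError("metastasis rates must lie in [0, 1]")

    @property
    def label(self) -> str:
        a, b = sorted((self.gene_a, self.gene_b))
        return pair_label(a, b)


@dataclass
class CohortSimSpec:
    """Conditions for a set of expression cohorts with planted survival.

    Expression marginals are Normal on a log-like scale (the pair
    pipeline is rank-based, so marginal shape is immaterial); survival
    is exponential with hazard lambda0 * HR^z under independent
    Uniform(0, censor_window) censoring.
    """

    n_cohorts: int = 6
    n_samples: int = 150
    n_genes: int = 400
    pair: PlantedPair = field(default_factory=PlantedPair)
    baseline_hazard: float = 0.12       # per time unit
    censor_window: float = 60.0         # administrative censoring horizon
    pair_sep: float = 0.5               # +/- delta of the pair genes around mu
    pair_sd: float = 0.25               # within-gene spread of the pair genes
    noise_sd: float = 1.0               # within-gene spread of noise genes
    noise_mean_sd: float = 2.0          # spread of gene-specific mean levels
    max_crossover: float = 0.01
    batch_transforms: tuple[str, ...] = (
        "identity", "exp", "affine", "cube", "logistic", "softplus",
    )
    n_candidate_noise_genes: int = 18
    deg_shift_range: tuple[float, float] = (0.15, 0.45)
    deg_mean_jitter: float = 0.3
    seed: int = 0
    cohort_seeds: tuple[int, ...] | None = None  # explicit per-cohort seeds

    def __post_init__(self) -> None:
        if self.censor_window <= 0:
            raise ValueError("censoring window must be > 0")
        from scipy.stats import norm

        crossover = float(norm.cdf(-2 * self.pair_sep / (np.sqrt(2) * self.pair_sd)))
        if crossover > self.max_crossover:
            raise ValueError(
                f"pair separation delta={self.pair_sep} gives crossover "
                f"probability {crossover:.3g} > bound {self.max_crossover}; "
                "increase pair_sep or noise_sd headroom"
            )
        for t in self.batch_transforms:
            if t not in BATCH_TRANSFORMS:
                raise ValueError(f"unknown batch transform {t!r}")
        if self.cohort_seeds is not None and len(self.cohort_seeds) != self.n_cohorts:
            raise ValueError("cohort_seeds must have one entry per cohort")


@dataclass
class CohortTruth:
    """Planted ground truth emitted with simulated cohorts."""

    pair: str
    hazard_ratio: float
    metastasis_rates: tuple[float, float]
    latent_state: dict[str, pd.Series]   # cohort -> z per sample
    candidate_genes: list[str]
    transforms: dict[str, str]


def simulate_cohorts(
    spec: CohortSimSpec, force_identity: bool = False
) -> tuple[list[ExpressionCohort], CohortTruth]:
    """Generate expression cohorts with one planted prognostic pair.

    Per sample a latent state z ~ Bernoulli(0.5) decides the pair
    orientation: for z = 1 gene A ~ N(mu + delta, pair_sd) and gene B ~
    N(mu - delta, pair_sd) (swapped for z = 0), with delta validated so
    the within-pair crossover probability stays below the configured bound.
    The pair contrast is deliberately small in absolute terms (delta
    and pair_sd well inside the noise-gene spread) so that only the
    A-versus-B comparison — not either gene's marginal level — carries
    the latent state.  Remaining genes are independent Normal noise
    with gene-specific mean levels (shared across cohorts) spread by
    *noise_mean_sd*; pairs of a noise gene with a planted gene are
    therefore either dominated by the level difference (and removed by
    the imbalance filter) or nearly uninformative about z.  Survival
    time ~ Exponential(lambda0 * HR^z); censoring ~ Uniform(0, window);
    metastasis ~ Bernoulli of the state rate.  Finally the cohort's
    strictly monotone batch transform distorts all expression values
    (identity everywhere when *force_identity*, for invariance checks).
    """
    pair = spec.pair
    gene_names = [f"G{i:04d}" for i in range(spec.n_genes)]
    # the planted pair occupies two reserved slots
    gene_names[0], gene_names[1] = pair.gene_a, pair.gene_b
    mu = 5.0
    n_deg = spec.n_candidate_noise_genes
    gene_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 40911]))
    gene_means = gene_rng.normal(mu, spec.noise_mean_sd, size=spec.n_genes)
    # candidate "DEG-like" genes (slots 2 .. 2+n_deg): comparable mean
    # levels and moderate subtype-linked shifts, emulating a real DEG list
    gene_means[2:2 + n_deg] = mu + gene_rng.uniform(
        -spec.deg_mean_jitter, spec.deg_mean_jitter, size=n_deg
    )
    lo, hi = spec.deg_shift_range
    deg_shift = gene_rng.uniform(lo, hi, size=n_deg) * gene_rng.choice(
        (-1.0, 1.0), size=n_deg
    )
    cohorts: list[ExpressionCohort] = []
    latent: dict[str, pd.Series] = {}
    transforms: dict[str, str] = {}
    if spec.cohort_seeds is not None:
        children = [np.random.SeedSequence([s, 555]) for s in spec.cohort_seeds]
    else:
        children = np.random.SeedSequence(spec.seed).spawn(spec.n_cohorts)
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        cid = f"COHORT{c + 1}"
        samples = [f"{cid}_S{i:03d}" for i in range(spec.n_samples)]
        z = rng.integers(0, 2, size=spec.n_samples)
        sgn = 2.0 * z - 1.0  # +1 for z=1, -1 for z=0
        expr = (
            gene_means[:, None]
            + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
        )
        expr[2:2 + n_deg] += deg_shift[:, None] * sgn[None, :]
        delta = spec.pair_sep * sgn
        expr[0] = rng.normal(mu + delta, spec.pair_sd)
        expr[1] = rng.normal(mu - delta, spec.pair_sd)

        hazard = spec.baseline_hazard * pair.hazard_ratio**z
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0, spec.censor_window, size=spec.n_samples)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        rate = np.where(z == 1, pair.metastasis_rates[0], pair.metastasis_rates[1])
        met = np.where(rng.uniform(size=spec.n_samples) < rate, "M1", "M0")

        tname = ("identity" if force_identity
                 else spec.batch_transforms[c % len(spec.batch_transforms)])
        expr_out = BATCH_TRANSFORMS[tname](expr)
        cohorts.append(
            ExpressionCohort(
                cohort_id=cid,
                expr=pd.DataFrame(expr_out, index=gene_names, columns=samples),
                clinical=pd.DataFrame(
                    {"time": time, "event": event, "metastasis": met},
                    index=pd.Index(samples, name="sample_id"),
                ),
            )
        )
        latent[cid] = pd.Series(z, index=samples)
        transforms[cid] = tname

    candidates = [pair.gene_a, pair.gene_b] + gene_names[2:2 + spec.n_candidate_noise_genes]
    truth = CohortTruth(
        pair=pair.label,
        hazard_ratio=pair.hazard_ratio,
        metastasis_rates=pair.metastasis_rates,
        latent_state=latent,
        candidate_genes=candidates,
        transforms=transforms,
    )
    return cohorts, truth


# --------------------------------------------------------------- toy reference

def toy_reference(
    seed: int = 0,
    length: int = 4000,
    n_snvs: int = 60,
    n_samples: int = 3,
    n_mismatch: int = 0,
) -> tuple[dict[str, str], list[MutationRecord], pd.DataFrame]:
    """A small random genome plus a MAF with known channel truth.

    Returns (reference dict {chrom: sequence}, mutation records, truth
    table with each SNV's expected channel).  *n_mismatch* planted
    reference-mismatch rows exercise the reject log.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 887]))
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=length))
    chrom = "chrToy"
    records: list[MutationRecord] = []
    truth_rows = []
    positions = rng.choice(np.arange(2, length - 1), size=n_snvs + n_mismatch,
                           replace=False)
    for i, pos1 in enumerate(np.sort(positions)):  # 1-based
        ref = seq[pos1 - 1]
        sample = f"TOY{i % n_samples}"
        if i < n_snvs:
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            ch = classify_substitution(ref, alt, seq[pos1 - 2], seq[pos1])
            truth_rows.append({"sample_id": sample, "pos": int(pos1),
                               "channel": ch.label})
        else:  # planted mismatch: report a wrong reference allele
            wrong = str(rng.choice([b for b in "ACGT" if b != ref]))
            alt = str(rng.choice([b for b in "ACGT" if b != wrong]))
            ref = wrong
        records.append(
            MutationRecord(sample, chrom, int(pos1), ref, alt, "SNV")
        )
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "pos", "channel"])
    return {chrom: seq}, records, truth


def write_toy_reference(out_dir: str | Path, seed: int = 0, **kwargs) -> dict[str, Path]:
    """Materialise the toy fixture as FASTA + MAF + truth TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref, records, truth = toy_reference(seed=seed, **kwargs)
    fasta = out / "toy.fasta"
    with open(fasta, "w") as fh:
        for chrom, seq in ref.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    maf = out / "toy.maf"
    write_maf(records, maf)
    truth_path = out / "toy_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"fasta": fasta, "maf": maf, "truth": truth_path}


# -------------------------------------------------------- null survival draws

def simulate_null_survival(
    n: int, seed: int, baseline_hazard: float = 0.03, censor_window: float = 60.0
) -> pd.DataFrame:
    """Survival data with no covariate effect, for calibration tests."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t_event = rng.exponential(1.0 / baseline_hazard, size=n)
    t_cens = rng.uniform(0, censor_window, size=n)
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        }
    )
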