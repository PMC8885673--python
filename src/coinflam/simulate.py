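"""Seeded synthetic-cohort generators.

These produce every input the pipeline consumes — expression matrices
with a gene-set partition and subject metadata, OTU count tables with
Greengenes-style lineages, and covariate tables (diet, T-cell
frequencies, analyte panels) — with the paired pre/post statistical
structure the analysis assumes.  Defaults emulate the pilot-trial
conditions: 25 paired subjects, a 307/1,067 inflammatory/regulatory
probe split, a modest post-supplement anti-inflammatory shift in the
composite index (about -12% on average with between-subject response
heterogeneity), 173 OTUs at roughly 20,600 reads/sample with
post-enriched butyrogenic and supplement families, analyte panels with
small paired effects, and covariates coupled to the index change
through a Gaussian copula.

All randomness flows from a single integer seed per artifact through
``numpy.random.default_rng``; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    AnalytePanel,
    ExpressionMatrix,
    GeneSetPartition,
    OtuCountTable,
    SubjectVisitPair,
)
from .errors import CoinflamError, InvalidDesignError

N_SUBSETS = 4  # discovery data subsets used for the grouped index mode


# ---------------------------------------------------------------------------
# designs / effect models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Trial-level cohort structure."""

    n_subjects: int = 25
    frac_high_risk_hla: float = 0.40
    frac_multi_autoantibody: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidDesignError("n_subjects must be >= 2")
        for name in ("frac_high_risk_hla", "frac_multi_autoantibody"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidDesignError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ExpressionEffectModel:
    """Generative model for log2 array intensities.

    Intensity of probe p for subject s at visit v:

        baseline_mean + probe_offset_p + subject_effect_s
        + visit_v * response_s * delta(set(p)) + noise

    where delta(set(p)) is ``delta_inflammatory`` or ``delta_regulatory``
    and response_s ~ N(1, subject_response_sd) is a per-subject response
    scale providing the between-subject heterogeneity seen in responder
    binning (set ``subject_response_sd=0`` for a homogeneous effect).
    """

    n_inflammatory: int = 307
    n_regulatory: int = 1067
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    subject_sd: float = 0.2
    delta_inflammatory: float = -0.60  # <= 0: anti-inflammatory shift
    delta_regulatory: float = 0.12  # >= 0
    noise_sd: float = 0.15
    subject_response_sd: float = 1.2

    def __post_init__(self) -> None:
        if self.n_inflammatory < 1 or self.n_regulatory < 1:
            raise InvalidDesignError("gene-set sizes must be >= 1")
        for name in ("baseline_sd", "subject_sd", "noise_sd",
                     "subject_response_sd"):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be >= 0")


#: Full 7-rank Greengenes-style lineages for the synthetic community.
DEFAULT_FAMILY_LINEAGES = (
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae",
    "k__Bacteria;p__Actinobacteria;c__Actinobacteria;o__Bifidobacteriales;f__Bifidobacteriaceae",
    "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Porphyromonadaceae",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Peptostreptococcaceae",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Mogibacteriaceae",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Veillonellaceae",
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae",
)

LACHNOSPIRACEAE = DEFAULT_FAMILY_LINEAGES[0]
BIFIDOBACTERIACEAE = DEFAULT_FAMILY_LINEAGES[2]
LACTOBACILLACEAE = DEFAULT_FAMILY_LINEAGES[3]


def _default_enrichment():
    # post-enriched butyrogenic/supplement families, pre-enriched others
    return [
        (LACHNOSPIRACEAE, 0.9),
        (BIFIDOBACTERIACEAE, 0.8),
        (LACTOBACILLACEAE, 0.8),
        (DEFAULT_FAMILY_LINEAGES[5], -0.5),  # Porphyromonadaceae
        (DEFAULT_FAMILY_LINEAGES[6], -0.5),  # Peptostreptococcaceae
        (DEFAULT_FAMILY_LINEAGES[7], -0.4),  # Mogibacteriaceae
    ]


@dataclass(frozen=True)
class CommunityEffectModel:
    """Dirichlet-multinomial model of the paired stool communities.

    ``concentration`` is the Dirichlet concentration over OTUs (a
    power-law default emulating a few dominant and many rare taxa);
    post-visit samples multiply the concentrations of OTUs in each
    enriched family by exp(log-fold).  ``fixed_depth=False`` draws each
    sample's depth from a Poisson around ``depth_mean`` (read counts vary
    per sample in real libraries).
    """

    n_otus: int = 173
    n_samples_per_visit: int = 25
    concentration: tuple | None = None
    depth_mean: float = 20600.0
    enriched_families: list = field(default_factory=_default_enrichment)
    family_pool: tuple = DEFAULT_FAMILY_LINEAGES
    frac_unassigned_family: float = 0.02
    fixed_depth: bool = False

    def __post_init__(self) -> None:
        if self.n_otus < 1 or self.n_samples_per_visit < 1:
            raise InvalidDesignError("counts must be >= 1")
        if self.depth_mean <= 0:
            raise InvalidDesignError("depth_mean must be > 0")
        if self.concentration is not None:
            conc = tuple(float(c) for c in self.concentration)
            if len(conc) == 0:
                raise InvalidDesignError("concentration vector is empty")
            if any(c <= 0 for c in conc):
                raise InvalidDesignError("concentration entries must be > 0")
            if len(conc) != self.n_otus:
                raise InvalidDesignError(
                    "concentration length must equal n_otus"
                )
            object.__setattr__(self, "concentration", conc)

    def concentration_vector(self) -> np.ndarray:
        if self.concentration is not None:
            return np.asarray(self.concentration, dtype=float)
        # power-law abundance profile, total mass ~25 (overdispersed counts)
        ranks = np.arange(1, self.n_otus + 1, dtype=float)
        conc = 1.0 / ranks
        return 25.0 * conc / conc.sum()


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

def _make_subjects(design: CohortDesign, rng: np.random.Generator):
    n = design.n_subjects
    n_high = int(round(design.frac_high_risk_hla * n))
    n_multi = int(round(design.frac_multi_autoantibody * n))
    hla = np.array(["high"] * n_high + ["low"] * (n - n_high))
    rng.shuffle(hla)
    aab = np.zeros(n, dtype=int)
    aab[rng.choice(n, size=n_multi, replace=False)] = 2
    singles = np.where(aab == 0)[0]
    n_single = min(len(singles), int(round(0.08 * n)))
    if n_single:
        aab[rng.choice(singles, size=n_single, replace=False)] = 1
    pairs = []
    for i in range(n):
        sid = f"P{i + 1:02d}"
        pairs.append(
            SubjectVisitPair(
                subject_id=sid,
                pre_sample_id=f"{sid}_pre",
                post_sample_id=f"{sid}_post",
                sex="F" if rng.random() < 0.64 else "M",
                age=float(rng.uniform(6.0, 17.7)),
                hla_risk=str(hla[i]),
                autoantibody_count=int(aab[i]),
                adherence=float(np.clip(rng.normal(92.0, 10.0), 52.0, 100.0)),
            )
        )
    return pairs


def generate_expression(
    design: CohortDesign, model: ExpressionEffectModel
) -> tuple[ExpressionMatrix, GeneSetPartition, list]:
    """Simulate the paired plasma-induced transcription assay.

    Returns the probes x (2 * n_subjects) log2 matrix, the gene-set
    partition (with probes tagged round-robin into four data subsets for
    the grouped index mode), and the subject/visit metadata.
    """
    rng = np.random.default_rng(design.seed)
    pairs = _make_subjects(design, rng)

    infl_ids = [f"INF_{i + 1:04d}" for i in range(model.n_inflammatory)]
    reg_ids = [f"REG_{i + 1:04d}" for i in range(model.n_regulatory)]
    probes = infl_ids + reg_ids
    subset_label = {
        p: f"subset{(i % N_SUBSETS) + 1}" for i, p in enumerate(probes)
    }
    partition = GeneSetPartition(
        inflammatory=frozenset(infl_ids),
        regulatory=frozenset(reg_ids),
        subset_label=subset_label,
    )

    n_probes, n_subj = len(probes), design.n_subjects
    probe_offset = rng.normal(0.0, model.baseline_sd, size=n_probes)
    subject_effect = rng.normal(0.0, model.subject_sd, size=n_subj)
    response = rng.normal(1.0, model.subject_response_sd, size=n_subj)
    delta = np.where(
        np.arange(n_probes) < model.n_inflammatory,
        model.delta_inflammatory,
        model.delta_regulatory,
    )

    cols, names = [], []
    for s, pair in enumerate(pairs):
        for visit, sample_id in (
            (0, pair.pre_sample_id),
            (1, pair.post_sample_id),
        ):
            noise = rng.normal(0.0, model.noise_sd, size=n_probes)
            cols.append(
                model.baseline_mean
                + probe_offset
                + subject_effect[s]
                + visit * response[s] * delta
                + noise
            )
            names.append(sample_id)
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(cols), index=probes, columns=names)
    )
    return matrix, partition, pairs


# ---------------------------------------------------------------------------
# OTU-table generator
# ---------------------------------------------------------------------------

def _assign_lineages(model: CommunityEffectModel, rng) -> pd.Series:
    lineages = {}
    n_unassigned = int(round(model.frac_unassigned_family * model.n_otus))
    for i in range(model.n_otus):
        otu = f"OTU_{i + 1:04d}"
        if i < model.n_otus - n_unassigned:
            fam = model.family_pool[i % len(model.family_pool)]
            lineages[otu] = f"{fam};g__Genus{i % 7 + 1};s__"
        else:
            # assigned only to order level: unmapped at family
            lineages[otu] = "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales"
    return pd.Series(lineages)


def generate_otu_table(
    model: CommunityEffectModel, seed: int | None = None
) -> OtuCountTable:
    """Dirichlet-multinomial paired community counts.

    Pre samples draw from the base concentration; post samples from the
    concentration with enriched-family entries multiplied by
    exp(log-fold enrichment).  Sample ids are ``pre_NN`` / ``post_NN``.
    """
    rng = np.random.default_rng(seed)
    lineages = _assign_lineages(model, rng)
    conc_pre = model.concentration_vector()
    conc_post = conc_pre.copy()
    for fam, log_fold in model.enriched_families:
        in_fam = lineages.str.startswith(fam).to_numpy()
        conc_post[in_fam] *= np.exp(log_fold)

    rows, ids = [], []
    for visit, conc in (("pre", conc_pre), ("post", conc_post)):
        for i in range(model.n_samples_per_visit):
            depth = (
                int(model.depth_mean)
                if model.fixed_depth
                else int(rng.poisson(model.depth_mean))
            )
            p = rng.dirichlet(conc)
            rows.append(rng.multinomial(depth, p))
            ids.append(f"{visit}_{i + 1:02d}")
    counts = pd.DataFrame(rows, index=ids, columns=lineages.index)
    return OtuCountTable(counts, lineages)


def visit_labels(table: OtuCountTable) -> pd.Series:
    """Map ``pre_NN`` / ``post_NN`` sample ids to their visit class."""
    return pd.Series(
        {s: str(s).split("_")[0] for s in table.sample_ids}
    )


# ---------------------------------------------------------------------------
# covariate generator
# ---------------------------------------------------------------------------

def coupled_covariate(
    delta,
    target_corr: float,
    rng: np.random.Generator,
    mean: float = 0.0,
    sd: float = 1.0,
) -> np.ndarray:
    """Gaussian coupling of a new covariate to a supplied vector.

    The supplied vector is standardised to z-scores; the covariate is
    ``target_corr * z + sqrt(1 - target_corr^2) * eps`` rescaled to the
    requested normal marginal, so its population correlation with the
    vector is exactly ``target_corr`` (and the sample correlation
    converges to it as n grows).
    """
    if not -1.0 <= target_corr <= 1.0:
        raise CoinflamError("target_corr must lie in [-1, 1]")
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 1 or delta.size < 2:
        raise CoinflamError("delta must be a 1-D vector with n >= 2")
    s = delta.std()
    if s == 0:
        raise CoinflamError("delta has zero variance")
    z = (delta - delta.mean()) / s
    eps = rng.normal(size=delta.size)
    coupled = target_corr * z + np.sqrt(1.0 - target_corr**2) * eps
    return mean + sd * coupled


@dataclass
class CovariateTables:
    """Generated covariate bundle keyed to a ΔI.I. vector."""

    delta_iicom_pct: pd.Series  # subject -> percent change in the index
    ffq: pd.DataFrame  # subject_id, kcal_per_day, fiber_g_per_day, ...
    tcell: pd.DataFrame  # subject_id, visit, pct_memory, pct_naive
    analytes: AnalytePanel


#: (analyte, unit, baseline mean, percent shift post) — shifts mirror the
#: trial's significantly modulated mediators; three null analytes included.
DEFAULT_ANALYTE_EFFECTS = (
    ("IL-12p40", "pg/ml", 120.0, -16.4),
    ("IL-13", "pg/ml", 12.0, -31.1),
    ("IL-15", "pg/ml", 4.0, -30.3),
    ("IL-18", "pg/ml", 180.0, -8.1),
    ("IL-28A", "pg/ml", 9.0, -6.7),
    ("CCL2", "pg/ml", 300.0, -8.6),
    ("CCL21", "pg/ml", 400.0, -6.4),
    ("CCL24", "pg/ml", 350.0, -10.4),
    ("TRAIL", "pg/ml", 40.0, 8.1),
    ("IL-6", "pg/ml", 6.0, 0.0),
    ("TNF-a", "pg/ml", 18.0, 0.0),
    ("IFN-g", "pg/ml", 10.0, 0.0),
)

#: (SCFA, unit, pre mean uM, fold change post)
DEFAULT_SCFA_EFFECTS = (
    ("butyrate", "uM", 0.94, 1.40),
    ("acetate", "uM", 40.0, 1.0),
    ("propionate", "uM", 2.2, 1.0),
    ("valerate", "uM", 0.4, 1.0),
    ("hexanoate", "uM", 0.3, 1.0),
)


def generate_covariates(
    design: CohortDesign,
    target_corr: float = 0.67,
    seed: int | None = None,
    delta_iicom_pct=None,
    fiber_corr: float = -0.40,
    analyte_noise_sd: float = 0.12,
) -> CovariateTables:
    """Generate FFQ, T-cell frequency, and analyte tables for a cohort.

    The change in the CD4 memory:naive ratio is coupled to the supplied
    (or generated) per-subject index percent change at ``target_corr``;
    fiber intake relative to the 14 g/1000 kcal guideline is coupled at
    ``fiber_corr``.  Analyte panels plant small paired mean shifts with
    multiplicative log-normal noise.
    """
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    n = design.n_subjects
    subjects = [f"P{i + 1:02d}" for i in range(n)]

    if delta_iicom_pct is None:
        delta = pd.Series(rng.normal(-12.0, 9.5, size=n), index=subjects)
    else:
        delta = pd.Series(np.asarray(delta_iicom_pct, dtype=float),
                          index=subjects)

    # --- FFQ: kcal and fiber; fiber %IOM coupled (negatively) to delta ---
    kcal = np.clip(rng.normal(1722.0, 480.0, size=n), 742.0, 2744.0)
    fiber_pct_iom = np.clip(
        coupled_covariate(delta.to_numpy(), fiber_corr, rng, mean=74.0, sd=22.0),
        10.0, 220.0,
    )
    fiber_g = fiber_pct_iom / 100.0 * 14.0 * kcal / 1000.0
    ffq = pd.DataFrame(
        {
            "subject_id": subjects,
            "kcal_per_day": kcal,
            "fiber_g_per_day": fiber_g,
            "soluble_fiber_g_per_day": fiber_g * rng.uniform(0.2, 0.4, size=n),
        }
    )

    # --- T cells: ratio percent change coupled to delta at target_corr ---
    ratio_change_pct = coupled_covariate(
        delta.to_numpy(), target_corr, rng, mean=-8.0, sd=14.0
    )
    naive_pre = rng.uniform(35.0, 60.0, size=n)
    ratio_pre = np.clip(rng.normal(0.55, 0.12, size=n), 0.2, 1.1)
    memory_pre = ratio_pre * naive_pre
    naive_post = np.clip(naive_pre + rng.normal(0.0, 2.0, size=n), 5.0, 95.0)
    memory_post = ratio_pre * (1.0 + ratio_change_pct / 100.0) * naive_post
    tcell = pd.DataFrame(
        {
            "subject_id": subjects * 2,
            "visit": ["pre"] * n + ["post"] * n,
            "pct_memory": np.clip(np.r_[memory_pre, memory_post], 0.5, 95.0),
            "pct_naive": np.r_[naive_pre, naive_post],
        }
    )

    # --- analyte panels ---
    rows = []
    for name, unit, base, shift_pct in DEFAULT_ANALYTE_EFFECTS:
        pre = base * rng.lognormal(0.0, 0.4, size=n)
        post = (
            pre
            * (1.0 + shift_pct / 100.0)
            * rng.lognormal(0.0, analyte_noise_sd, size=n)
        )
        for s, a, b in zip(subjects, pre, post):
            rows.append((s, "pre", name, float(a), unit))
            rows.append((s, "post", name, float(b), unit))
    for name, unit, pre_mean, fold in DEFAULT_SCFA_EFFECTS:
        pre = pre_mean * rng.lognormal(-0.35, 0.85, size=n)
        post = pre * fold * rng.lognormal(0.0, 0.35, size=n)
        for s, a, b in zip(subjects, pre, post):
            rows.append((s, "pre", name, float(a), unit))
            rows.append((s, "post", name, float(b), unit))
    analytes = AnalytePanel(
        pd.DataFrame(
            rows, columns=["subject_id", "visit", "analyte", "value", "unit"]
        )
    )
    return CovariateTables(
        delta_iicom_pct=delta, ffq=ffq, tcell=tcell, analytes=analytes
    )
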