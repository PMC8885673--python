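"""Taxonomy-aware OTU-table analysis.

Rank collapsing with explicit pooling of reads unassigned at the target
rank (so mapped-read fractions can be reported), alpha diversity
(Shannon, richness), Bray-Curtis beta diversity with classical PCoA, and
a linear-discriminant-analysis effect-size procedure for differential
abundance between sample classes.

The effect-size procedure follows the one-against-all two-class scheme:
per-feature Kruskal-Wallis screen (equivalent to a Wilcoxon rank-sum
test for two classes), then a bootstrap-averaged LDA effect size on
scaled relative abundances, reported on a log10 scale.  Features are
called significant when the screen p-value is <= alpha AND the absolute
LDA score reaches the cutoff (2.0 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .datatypes import RANKS, OtuCountTable, lineage_prefix
from .errors import (
    CoinflamError,
    DegenerateClassError,
    EmptySampleError,
    InvalidDistanceError,
)

UNMAPPED = "unmapped"


# ---------------------------------------------------------------------------
# rank collapsing
# ---------------------------------------------------------------------------

@dataclass
class RankCollapse:
    """Result of collapsing an OTU table to a taxonomic rank."""

    table: OtuCountTable
    rank: str
    mapped_fraction: float  # fraction of reads assigned at `rank`
    n_mapped_reads: int
    n_total_reads: int


def collapse_to_rank(table: OtuCountTable, rank: str) -> RankCollapse:
    """Sum counts over OTUs sharing the lineage prefix through ``rank``.

    OTUs whose lineage is unassigned at ``rank`` are pooled into an
    explicit ``unmapped`` feature rather than dropped, so per-sample
    totals are conserved exactly and the mapped-read fraction can be
    reported.
    """
    if rank not in RANKS:
        raise CoinflamError(f"unknown rank {rank!r}; expected one of {RANKS}")
    groups: dict[str, list] = {}
    for otu in table.otu_ids:
        prefix = lineage_prefix(table.lineages[otu], rank)
        groups.setdefault(prefix if prefix is not None else UNMAPPED, []).append(otu)

    cols, lineages = {}, {}
    for feature, otus in sorted(groups.items()):
        cols[feature] = table.counts[otus].sum(axis=1)
        lineages[feature] = "" if feature == UNMAPPED else feature
    counts = pd.DataFrame(cols, index=table.sample_ids)
    collapsed = OtuCountTable(counts, pd.Series(lineages))

    total = int(table.counts.to_numpy().sum())
    unmapped = int(counts[UNMAPPED].sum()) if UNMAPPED in counts else 0
    mapped = total - unmapped
    return RankCollapse(
        table=collapsed,
        rank=rank,
        mapped_fraction=mapped / total if total else float("nan"),
        n_mapped_reads=mapped,
        n_total_reads=total,
    )


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon_index(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero proportions.

    Base 2 by default, i.e. bits.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise EmptySampleError("Shannon index undefined for an empty sample")
    if (c < 0).any():
        raise CoinflamError("counts must be non-negative")
    p = c[c > 0] / c.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def richness(counts) -> int:
    """Number of features with strictly positive count."""
    c = np.asarray(counts, dtype=float)
    return int((c > 0).sum())


def alpha_diversity_table(table: OtuCountTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon index and richness."""
    rows = {
        s: {
            "shannon": shannon_index(table.counts.loc[s].to_numpy(), base=base),
            "richness": richness(table.counts.loc[s].to_numpy()),
        }
        for s in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(sample_a, sample_b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum_a + sum_b), in [0, 1].

    Semi-metric: symmetric with zero self-distance, but the triangle
    inequality may be violated.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise CoinflamError("samples must have equal length")
    if a.sum() <= 0 or b.sum() <= 0:
        raise EmptySampleError("Bray-Curtis undefined for a zero-total sample")
    return float(braycurtis(a, b))


def bray_curtis_matrix(table: OtuCountTable) -> pd.DataFrame:
    """Square symmetric Bray-Curtis dissimilarity matrix over all samples."""
    ids = list(table.sample_ids)
    n = len(ids)
    mat = np.zeros((n, n))
    arrs = [table.counts.loc[s].to_numpy(dtype=float) for s in ids]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(arrs[i], arrs[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame  # samples x retained positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    negative_eigenvalues: np.ndarray  # the negative subset (dropped axes)
    proportion_explained: np.ndarray


def pcoa(distance_matrix) -> PcoaResult:
    """Principal Coordinate Analysis via the double-centred Gower matrix.

    Axes are ordered by eigenvalue; axes with negative eigenvalues (which
    arise for semi-metrics such as Bray-Curtis) are reported but dropped
    from the returned coordinates.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        ids = list(distance_matrix.index)
        mat = distance_matrix.to_numpy(dtype=float)
    else:
        mat = np.asarray(distance_matrix, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InvalidDistanceError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise InvalidDistanceError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0, atol=1e-12):
        raise InvalidDistanceError("distance matrix must have a zero diagonal")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ord_res = _skbio_pcoa(DistanceMatrix(mat, ids), method="eigh")
    eigvals = ord_res.eigvals.to_numpy()
    keep = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    coords = ord_res.samples.loc[:, keep]
    coords.index = pd.Index(ids)
    coords.columns = [f"PC{i + 1}" for i in range(keep.sum())]
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eigvals,
        negative_eigenvalues=eigvals[eigvals < 0],
        proportion_explained=ord_res.proportion_explained.to_numpy()[keep],
    )


# ---------------------------------------------------------------------------
# LDA effect size
# ---------------------------------------------------------------------------

def _class_arrays(labels, sample_ids):
    lab = pd.Series(labels)
    if not set(sample_ids).issubset(set(lab.index)):
        lab = pd.Series(list(labels), index=sample_ids)
    lab = lab.loc[sample_ids]
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise DegenerateClassError(
            f"exactly 2 classes required, got {len(classes)}"
        )
    for c in classes:
        if (lab == c).sum() < 2:
            raise DegenerateClassError(f"class {c!r} has fewer than 2 samples")
    return lab, classes


def lda_effect_size(
    table: OtuCountTable,
    class_labels,
    alpha: float = 0.05,
    lda_cutoff: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
    abundance_scale: float = 1_000_000.0,
) -> pd.DataFrame:
    """Two-class differential-abundance effect sizes.

    Per feature: relative abundances scaled to ``abundance_scale`` per
    sample (one million by default, the normalisation under which the
    conventional |LDA| >= 2 cutoff is interpreted); Kruskal-Wallis screen
    at ``alpha``; surviving features scored
    jointly by a bootstrap-averaged linear discriminant.  The score for
    feature f is

        sign * log10(1 + (|dm_f| + |w_f * d_LD|) / 2)

    averaged over ``n_boot`` within-class resamples, where ``dm_f`` is the
    between-class difference of feature means, ``w_f`` the unit LDA
    loading and ``d_LD`` the between-class separation along the
    discriminant.  The sign is positive when the feature is enriched in
    the class that sorts last.

    Returns a DataFrame indexed by feature with columns ``enriched_class``,
    ``p_value``, ``lda_score`` (NaN for features failing the screen) and
    ``significant``.
    """
    if not 0 < alpha <= 1:
        raise CoinflamError("alpha must be in (0, 1]")
    if lda_cutoff < 0:
        raise CoinflamError("lda_cutoff must be >= 0")
    lab, classes = _class_arrays(class_labels, list(table.sample_ids))
    rng = np.random.default_rng(seed)

    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise EmptySampleError("zero-total sample in OTU table")
    X = counts / totals * abundance_scale  # samples x features
    features = list(table.otu_ids)
    y = (lab.to_numpy() == classes[1]).astype(int)
    idx0, idx1 = np.where(y == 0)[0], np.where(y == 1)[0]

    pvals, enriched = [], []
    for j in range(X.shape[1]):
        a, b = X[idx0, j], X[idx1, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals.append(1.0)
        else:
            pvals.append(float(stats.kruskal(a, b).pvalue))
        enriched.append(classes[1] if b.mean() > a.mean() else classes[0])
    pvals = np.asarray(pvals)

    candidate = np.where(pvals <= alpha)[0]
    scores = np.full(len(features), np.nan)
    if candidate.size:
        acc = np.zeros(candidate.size)
        for _ in range(n_boot):
            bi0 = rng.choice(idx0, size=idx0.size, replace=True)
            bi1 = rng.choice(idx1, size=idx1.size, replace=True)
            bidx = np.concatenate([bi0, bi1])
            Xb = X[np.ix_(bidx, candidate)].copy()
            # jitter regularises zero within-class variance, as the
            # standard effect-size tool does
            Xb += rng.normal(0.0, np.maximum(0.05 * np.abs(Xb), 1e-5))
            yb = np.concatenate([np.zeros(bi0.size), np.ones(bi1.size)])
            acc += _lda_effect_once(Xb, yb)
        mean_effect = acc / n_boot
        sign = np.array(
            [1.0 if enriched[j] == classes[1] else -1.0 for j in candidate]
        )
        scores[candidate] = sign * np.log10(1.0 + mean_effect)

    out = pd.DataFrame(
        {
            "enriched_class": enriched,
            "p_value": pvals,
            "lda_score": scores,
            "significant": (pvals <= alpha) & (np.abs(scores) >= lda_cutoff),
        },
        index=pd.Index(features, name="feature"),
    )
    return out


def _lda_effect_once(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Per-feature combined effect for one bootstrap draw."""
    means0 = Xb[yb == 0].mean(axis=0)
    means1 = Xb[yb == 1].mean(axis=0)
    dm = np.abs(means1 - means0)
    try:
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
        lda.fit(Xb, yb)
        w = lda.scalings_[:, 0]
    except Exception:
        return dm  # fall back to the raw mean difference
    norm = np.linalg.norm(w)
    if norm == 0 or not np.isfinite(norm):
        return dm
    w = w / norm
    ld = Xb @ w
    sep = abs(ld[yb == 1].mean() - ld[yb == 0].mean())
    return (dm + np.abs(w) * sep) / 2.0


class LefseModel:
    """Model-style wrapper around :func:`lda_effect_size`.

    Parameters
    ----------
    table : OtuCountTable
        Usually first collapsed to the rank of interest.
    class_labels : mapping or sequence
        Sample id -> class (e.g. visit "pre"/"post").
    """

    def __init__(self, table: OtuCountTable, class_labels):
        self.table = table
        self.class_labels = class_labels

    def fit(
        self,
        alpha: float = 0.05,
        lda_cutoff: float = 2.0,
        n_boot: int = 30,
        seed: int | None = None,
        abundance_scale: float = 1_000_000.0,
    ) -> "LefseResults":
        table = lda_effect_size(
            self.table,
            self.class_labels,
            alpha=alpha,
            lda_cutoff=lda_cutoff,
            n_boot=n_boot,
            seed=seed,
            abundance_scale=abundance_scale,
        )
        return LefseResults(self, table, alpha, lda_cutoff)


class LefseResults:
    def __init__(self, model, table, alpha, lda_cutoff):
        self.model = model
        self.table = table
        self.alpha = alpha
        self.lda_cutoff = lda_cutoff

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "LDA effect-size differential abundance",
            f"  features tested: {len(self.table)}",
            f"  significant (p <= {self.alpha:g}, |LDA| >= {self.lda_cutoff:g}):"
            f" {len(sig)}",
        ]
        for feat, row in sig.iterrows():
            lines.append(
                f"    {feat}: enriched in {row['enriched_class']}, "
                f"LDA = {row['lda_score']:.2f}, p = {row['p_value']:.3g}"
            )
        return "\n".join(lines)
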