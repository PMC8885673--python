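"""Per-transcript paired differential induction with FDR control.

With exactly two paired conditions the per-probe ANOVA reduces to the
paired t-test (F = t**2), which is what is implemented.  Benjamini-
Hochberg adjustment is applied within the supplied probe subset only by
default, so the "x of m index probes at FDR < rate" count refers to the
index transcripts and not the whole array.

Also provided: per-subject log2 fold-change signatures, Pearson
correlation of a signature to a reference signature, and a generic
activation z-score for a user-supplied signed regulator network,

    z = (n_agree - n_disagree) / sqrt(n_overlap),

with activation called at z >= 2 and inhibition at z <= -2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SubjectVisitPair
from .errors import (
    CoinflamError,
    EmptyInputError,
    MissingSampleError,
    NoEvidenceError,
)


def fold_change_signature(
    matrix: ExpressionMatrix, pair: SubjectVisitPair
) -> pd.Series:
    """Per-probe log2 fold change (post - pre) for one subject."""
    for sid in (pair.pre_sample_id, pair.post_sample_id):
        if sid not in matrix.sample_ids:
            raise MissingSampleError(f"sample {sid!r} not in matrix")
    return matrix.values[pair.post_sample_id] - matrix.values[pair.pre_sample_id]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on positions."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise EmptyInputError("p_values must be a non-empty 1-D array")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise CoinflamError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_differential_test(
    matrix: ExpressionMatrix,
    pairs,
    subset=None,
    fdr_rate: float = 0.20,
) -> pd.DataFrame:
    """Paired t-test per probe with BH adjustment across ``subset``.

    Returns a DataFrame indexed by probe id with columns
    ``mean_log_fold_change``, ``p_value``, ``q_value``, ``passes_fdr``.
    The pass flag uses the strict ``q < fdr_rate`` convention.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise CoinflamError("need at least 3 subject pairs")
    if not 0 < fdr_rate <= 1:
        raise CoinflamError("fdr_rate must be in (0, 1]")
    if subset is None:
        probes = list(matrix.probe_ids)
    else:
        probes = [p for p in matrix.probe_ids if p in set(subset)]
        extra = set(subset) - set(matrix.probe_ids)
        if extra:
            raise CoinflamError(f"subset probes not in matrix: {sorted(extra)[:5]}")
    if not probes:
        raise EmptyInputError("probe subset is empty")

    pre = matrix.values.loc[probes, [p.pre_sample_id for p in pairs]].to_numpy()
    post = matrix.values.loc[probes, [p.post_sample_id for p in pairs]].to_numpy()
    diffs = post - pre
    res = stats.ttest_rel(post, pre, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    # a probe with identical pre/post columns has an undefined t; p -> 1
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "mean_log_fold_change": diffs.mean(axis=1),
            "p_value": pvals,
            "q_value": qvals,
            "passes_fdr": qvals < fdr_rate,
        },
        index=pd.Index(probes, name="probe_id"),
    )


def signature_correlation(fold_changes, reference) -> float:
    """Pearson correlation between a signature and a reference signature."""
    x = np.asarray(fold_changes, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise CoinflamError("signatures must be equal-length 1-D, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CoinflamError("correlation undefined for a constant signature")
    return float(stats.pearsonr(x, y).statistic)


class SignedRegulatorNetwork:
    """One regulator's expected target directions: target id -> +1/-1."""

    def __init__(self, regulator: str, edges: dict):
        self.regulator = regulator
        self.edges = {}
        for target, sign in dict(edges).items():
            if sign not in (1, -1):
                raise CoinflamError(
                    f"{regulator}: sign for {target!r} must be +1 or -1"
                )
            self.edges[target] = int(sign)
        if not self.edges:
            raise CoinflamError(f"{regulator}: network has no edges")


def regulator_activation_z(
    network: SignedRegulatorNetwork, observed_directions: dict
) -> float:
    """Activation z-score of a regulator given observed target directions.

    ``observed_directions`` maps probe id -> +1 (induced) / -1 (repressed).
    Agreement means expected sign times observed sign is +1.
    """
    overlap = [t for t in network.edges if t in observed_directions]
    if not overlap:
        raise NoEvidenceError(
            f"{network.regulator}: no overlap with observed directions"
        )
    agree = 0
    for t in overlap:
        obs = observed_directions[t]
        if obs not in (1, -1):
            raise CoinflamError(f"observed direction for {t!r} must be +1 or -1")
        agree += 1 if network.edges[t] * obs == 1 else -1
    return agree / np.sqrt(len(overlap))


class PairedInductionModel:
    """Cohort-level differential-induction analysis.

    Wraps :func:`paired_differential_test` and derives the summary
    quantities of interest: the number and fraction of probes passing the
    FDR screen, the cohort-mean fold-change signature, and (optionally)
    its correlation to a reference signature.
    """

    def __init__(self, matrix: ExpressionMatrix, pairs, subset=None):
        self.matrix = matrix
        self.pairs = list(pairs)
        self.subset = None if subset is None else set(subset)

    def fit(self, fdr_rate: float = 0.20) -> "PairedInductionResults":
        table = paired_differential_test(
            self.matrix, self.pairs, self.subset, fdr_rate
        )
        return PairedInductionResults(self, table, fdr_rate)


class PairedInductionResults:
    def __init__(self, model, table: pd.DataFrame, fdr_rate: float):
        self.model = model
        self.table = table
        self.fdr_rate = fdr_rate
        self.n_tested = len(table)
        self.n_significant = int(table["passes_fdr"].sum())

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.n_tested

    def significant_probes(self) -> list:
        return list(self.table.index[self.table["passes_fdr"]])

    def mean_signature(self) -> pd.Series:
        return self.table["mean_log_fold_change"]

    def reference_correlation(self, reference: pd.Series, probes=None) -> float:
        """Pearson r of the significant-probe mean signature to a reference."""
        if probes is None:
            probes = self.significant_probes()
        probes = [p for p in probes if p in reference.index]
        if len(probes) < 3:
            raise CoinflamError("fewer than 3 shared probes with reference")
        return signature_correlation(
            self.table.loc[probes, "mean_log_fold_change"].to_numpy(),
            reference.loc[probes].to_numpy(),
        )

    def summary(self) -> str:
        return (
            "Paired differential induction\n"
            f"  probes tested: {self.n_tested}\n"
            f"  FDR < {self.fdr_rate:g}: {self.n_significant} "
            f"({100 * self.fraction_significant:.1f}%)"
        )
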