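"""Composite inflammatory index.

The index for a sample is the ratio of the mean log2 intensity of the
"inflammatory" probe set to that of the "regulatory" probe set of the
plasma-induced transcription assay.  High values reflect inflammatory
bias, low values regulatory bias.  A paired pre/post design quantifies
the supplement effect as a percent change per subject, with subjects
binned into responder classes at a +/-5% threshold.

Two constructions are provided (the published construction averages the
ratio over discovery data subsets, whose composition is not public):

``mode="pooled"``
    ratio of set-wide mean log intensities (default).
``mode="grouped"``
    unweighted mean of the per-subset ratios, using the partition's
    ``subset_label`` tags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSetPartition, SubjectVisitPair
from .errors import (
    CoinflamError,
    DegenerateTestError,
    MissingProbeError,
    UndefinedRatioError,
)

RESPONDER_CLASSES = ("reduced", "increased", "stable")


def _set_mean(matrix: ExpressionMatrix, probes, sample_id, scale: str) -> float:
    vals = matrix.values.loc[list(probes), sample_id].to_numpy(dtype=float)
    if scale == "raw":
        vals = np.exp2(vals)
    return float(vals.mean())


def compute_iicom(
    matrix: ExpressionMatrix,
    partition: GeneSetPartition,
    sample_id,
    *,
    mode: str = "pooled",
    scale: str = "log",
) -> float:
    """Composite inflammatory index for one sample.

    Parameters
    ----------
    mode : {"pooled", "grouped"}
        Pooled: single inflammatory/regulatory mean ratio.  Grouped:
        unweighted mean of that ratio within each ``subset_label`` stratum.
    scale : {"log", "raw"}
        Whether means are taken on the stored log2 intensities (default)
        or on linearised ``2**x`` intensities.
    """
    if mode not in ("pooled", "grouped"):
        raise CoinflamError(f"unknown mode {mode!r}")
    if scale not in ("log", "raw"):
        raise CoinflamError(f"unknown scale {scale!r}")
    missing = partition.all_probes - set(matrix.probe_ids)
    if missing:
        raise MissingProbeError(missing)

    if mode == "pooled":
        strata = [(partition.inflammatory, partition.regulatory)]
    else:
        if not partition.subset_label:
            raise CoinflamError("grouped mode requires subset_label tags")
        labels = sorted(set(partition.subset_label.values()))
        strata = []
        for lab in labels:
            tagged = {p for p, l in partition.subset_label.items() if l == lab}
            infl = partition.inflammatory & tagged
            reg = partition.regulatory & tagged
            if not infl or not reg:
                raise CoinflamError(
                    f"subset {lab!r} lacks probes in one of the gene sets"
                )
            strata.append((infl, reg))

    ratios = []
    for infl, reg in strata:
        num = _set_mean(matrix, infl, sample_id, scale)
        den = _set_mean(matrix, reg, sample_id, scale)
        if den == 0:
            raise UndefinedRatioError("regulatory mean intensity is zero")
        ratios.append(num / den)
    return float(np.mean(ratios))


def percent_change(pre: float, post: float) -> float:
    """Signed percent change 100*(post - pre)/pre."""
    if pre == 0:
        raise UndefinedRatioError("pre value is zero; percent change undefined")
    return 100.0 * (post - pre) / pre


def classify_responder(pct_change: float, threshold: float = 5.0) -> str:
    """Bin a percent change into reduced / increased / stable.

    Strict inequalities: a change of exactly +/-threshold is "stable".
    """
    if threshold <= 0:
        raise CoinflamError("responder threshold must be positive")
    if pct_change < -threshold:
        return "reduced"
    if pct_change > threshold:
        return "increased"
    return "stable"


def paired_t_one_tailed(pre, post, direction: str = "less"):
    """One-tailed paired t-test on post - pre differences.

    ``direction="less"`` tests whether post values are lower than pre
    (the anti-inflammatory alternative for the index).

    Returns
    -------
    (t, p) : tuple of float
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if direction not in ("less", "greater"):
        raise CoinflamError("direction must be 'less' or 'greater'")
    if pre.shape != post.shape or pre.ndim != 1:
        raise CoinflamError("pre and post must be equal-length 1-D arrays")
    if pre.size < 3:
        raise CoinflamError("need at least 3 pairs for a paired t-test")
    if np.allclose(post - pre, 0):
        raise DegenerateTestError("all paired differences are zero")
    res = stats.ttest_rel(post, pre, alternative=direction)
    return float(res.statistic), float(res.pvalue)


@dataclass
class IndexResult:
    """Per-subject index outcome."""

    subject_id: str
    iicom_pre: float
    iicom_post: float
    percent_change: float
    responder_class: str


class InflammatoryIndexModel:
    """Paired pre/post composite-index analysis for a cohort.

    Parameters
    ----------
    matrix : ExpressionMatrix
    partition : GeneSetPartition
    pairs : sequence of SubjectVisitPair
    mode, scale : passed through to :func:`compute_iicom`.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        partition: GeneSetPartition,
        pairs,
        *,
        mode: str = "pooled",
        scale: str = "log",
    ):
        self.matrix = matrix
        self.partition = partition
        self.pairs = list(pairs)
        self.mode = mode
        self.scale = scale
        if not self.pairs:
            raise CoinflamError("no subject pairs supplied")
        for p in self.pairs:
            for sid in (p.pre_sample_id, p.post_sample_id):
                if sid not in matrix.sample_ids:
                    raise CoinflamError(f"sample {sid!r} not in matrix")

    def fit(
        self, direction: str = "less", responder_threshold: float = 5.0
    ) -> "InflammatoryIndexResults":
        rows = []
        for p in self.pairs:
            pre = compute_iicom(
                self.matrix, self.partition, p.pre_sample_id,
                mode=self.mode, scale=self.scale,
            )
            post = compute_iicom(
                self.matrix, self.partition, p.post_sample_id,
                mode=self.mode, scale=self.scale,
            )
            pct = percent_change(pre, post)
            rows.append(
                IndexResult(p.subject_id, pre, post, pct,
                            classify_responder(pct, responder_threshold))
            )
        return InflammatoryIndexResults(self, rows, direction, responder_threshold)


class InflammatoryIndexResults:
    """Results of :meth:`InflammatoryIndexModel.fit`."""

    def __init__(self, model, rows, direction, responder_threshold):
        self.model = model
        self.rows = rows
        self.direction = direction
        self.responder_threshold = responder_threshold
        self.per_subject = pd.DataFrame(
            [vars(r) for r in rows]
        ).set_index("subject_id")
        pre = self.per_subject["iicom_pre"].to_numpy()
        post = self.per_subject["iicom_post"].to_numpy()
        self.mean_pre = float(pre.mean())
        self.sd_pre = float(pre.std(ddof=1)) if pre.size > 1 else float("nan")
        self.mean_post = float(post.mean())
        self.sd_post = float(post.std(ddof=1)) if post.size > 1 else float("nan")
        self.t_statistic, self.p_value = paired_t_one_tailed(pre, post, direction)
        cls = self.per_subject["responder_class"]
        self.responder_counts = {c: int((cls == c).sum()) for c in RESPONDER_CLASSES}

    def summary(self) -> str:
        lines = [
            "Composite inflammatory index, paired pre/post analysis",
            f"  subjects: {len(self.rows)}",
            f"  I.I. pre : {self.mean_pre:.3f} +/- {self.sd_pre:.3f} (mean +/- sd)",
            f"  I.I. post: {self.mean_post:.3f} +/- {self.sd_post:.3f}",
            f"  paired t ({self.direction}, 1-tail): t = {self.t_statistic:.3f},"
            f" p = {self.p_value:.4f}",
            f"  responders (|change| > {self.responder_threshold:g}%): "
            + ", ".join(
                f"{k} = {v}" for k, v in self.responder_counts.items()
            ),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": len(self.rows),
            "mean_pre": self.mean_pre,
            "sd_pre": self.sd_pre,
            "mean_post": self.mean_post,
            "sd_post": self.sd_post,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "direction": self.direction,
            "responder_threshold": self.responder_threshold,
            "responder_counts": self.responder_counts,
        }
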