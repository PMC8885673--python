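"""Core data containers shared across the analysis stages.

Tabular payloads live in pandas objects; these thin wrappers pin down the
orientation conventions (probes x samples for expression, samples x OTUs
for counts) and validate the invariants the downstream statistics assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoinflamError, EmptySampleError

VISITS = ("pre", "post")

#: Greengenes-style rank order and prefixes, kingdom through species.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass
class ExpressionMatrix:
    """Log2-scale induced-transcription intensities, probes x samples."""

    values: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise CoinflamError("duplicate probe ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise CoinflamError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise CoinflamError("expression matrix contains non-finite values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSetPartition:
    """Disjoint inflammatory / regulatory probe sets defining the index.

    ``subset_label`` optionally tags each probe with the data subset it was
    discovered in; the grouped index mode averages the inflammatory-to-
    regulatory ratio within each subset before combining.
    """

    inflammatory: frozenset
    regulatory: frozenset
    subset_label: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inflammatory", frozenset(self.inflammatory))
        object.__setattr__(self, "regulatory", frozenset(self.regulatory))
        if not self.inflammatory or not self.regulatory:
            raise CoinflamError("both gene sets must be non-empty")
        if self.inflammatory & self.regulatory:
            raise CoinflamError("inflammatory and regulatory sets overlap")

    @property
    def all_probes(self) -> frozenset:
        return self.inflammatory | self.regulatory


@dataclass(frozen=True)
class SubjectVisitPair:
    """Subject metadata binding one pre sample to one post sample."""

    subject_id: str
    pre_sample_id: str
    post_sample_id: str
    sex: str = "unknown"
    age: float = float("nan")
    hla_risk: str = "low"  # {"high", "low"}
    autoantibody_count: int = 0
    adherence: float = float("nan")  # percent of doses taken

    def __post_init__(self) -> None:
        if self.pre_sample_id == self.post_sample_id:
            raise CoinflamError(
                f"subject {self.subject_id}: pre and post sample ids coincide"
            )
        if self.autoantibody_count < 0:
            raise CoinflamError("autoantibody_count must be >= 0")


@dataclass
class OtuCountTable:
    """Samples x OTUs integer counts with a Greengenes-style lineage per OTU."""

    counts: pd.DataFrame  # index = sample ids, columns = OTU ids
    lineages: pd.Series  # OTU id -> "k__...;p__...;...;s__..."

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise CoinflamError("OTU counts must be non-negative")
        missing = self.counts.columns.difference(self.lineages.index)
        if len(missing):
            raise CoinflamError(f"OTUs without lineage: {list(missing)[:5]}")
        self.lineages = self.lineages.loc[self.counts.columns]

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    def sample_counts(self, sample_id) -> np.ndarray:
        row = self.counts.loc[sample_id].to_numpy()
        if row.sum() == 0:
            raise EmptySampleError(f"sample {sample_id} has zero total counts")
        return row


@dataclass
class AnalytePanel:
    """Long-format per-subject, per-visit analyte concentrations.

    Columns: subject_id, visit ("pre"/"post"), analyte, value, unit.
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "visit", "analyte", "value")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise CoinflamError(f"analyte panel missing column {col!r}")
        if "unit" not in self.data.columns:
            self.data = self.data.assign(unit="")
        bad_visits = set(self.data["visit"]) - set(VISITS)
        if bad_visits:
            raise CoinflamError(f"unknown visit labels: {sorted(bad_visits)}")
        if (self.data["value"] < 0).any():
            raise CoinflamError("analyte concentrations must be >= 0")
        dup = self.data.duplicated(["subject_id", "visit", "analyte"])
        if dup.any():
            raise CoinflamError("duplicate (subject, visit, analyte) rows")

    def analytes(self) -> list:
        return sorted(self.data["analyte"].unique())

    def paired_values(self, analyte: str) -> pd.DataFrame:
        """Wide subject x {pre, post} values for one analyte (complete pairs)."""
        sub = self.data[self.data["analyte"] == analyte]
        wide = sub.pivot(index="subject_id", columns="visit", values="value")
        return wide.reindex(columns=list(VISITS)).dropna()


def parse_lineage(lineage: str) -> dict:
    """Split ``k__Bacteria;p__Firmicutes;...`` into rank -> name.

    Ranks that are absent or empty after the prefix (``f__``) are omitted,
    which is how truncated Greengenes assignments signal "unmapped below
    this rank".
    """
    out: dict = {}
    for token in str(lineage).split(";"):
        token = token.strip()
        for rank, prefix in zip(RANKS, RANK_PREFIXES):
            if token.startswith(prefix):
                name = token[len(prefix):].strip()
                if name:
                    out[rank] = name
                break
    return out


def lineage_prefix(lineage: str, rank: str) -> str | None:
    """Lineage truncated at ``rank`` (inclusive), or None if unassigned there."""
    if rank not in RANKS:
        raise CoinflamError(f"unknown rank {rank!r}; expected one of {RANKS}")
    parsed = parse_lineage(lineage)
    depth = RANKS.index(rank)
    if RANKS[depth] not in parsed:
        return None
    parts = []
    for r, p in zip(RANKS[: depth + 1], RANK_PREFIXES[: depth + 1]):
        parts.append(p + parsed.get(r, ""))
    return ";".join(parts)
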