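"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as TSV (first column = probe id, header =
sample ids); gene sets as GMT; OTU tables as TSV with rows = OTUs,
columns = samples and a final semicolon-delimited ``lineage`` column;
subject metadata, analyte panels and covariates as CSV; distance
matrices as square TSV; signed regulator networks as three-column TSV
(regulator, target, sign).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import (
    AnalytePanel,
    ExpressionMatrix,
    GeneSetPartition,
    OtuCountTable,
    SubjectVisitPair,
)
from .differential import SignedRegulatorNetwork
from .errors import CoinflamError


# --- expression ------------------------------------------------------------

def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.rename_axis("probe_id").to_csv(path, sep="\t")


# --- gene sets (GMT) -------------------------------------------------------

def read_gmt_partition(path) -> GeneSetPartition:
    """Parse a GMT file into the inflammatory/regulatory partition.

    Set names are ``inflammatory`` / ``regulatory``, optionally suffixed
    ``|<subset>`` to tag probes with a data-subset label.
    """
    inflammatory, regulatory, subset_label = set(), set(), {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise CoinflamError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = fields
        base, _, subset = name.partition("|")
        if base == "inflammatory":
            inflammatory.update(genes)
        elif base == "regulatory":
            regulatory.update(genes)
        else:
            raise CoinflamError(f"unexpected GMT set name {name!r}")
        if subset:
            for g in genes:
                subset_label[g] = subset
    return GeneSetPartition(
        inflammatory=frozenset(inflammatory),
        regulatory=frozenset(regulatory),
        subset_label=subset_label,
    )


def write_gmt_partition(partition: GeneSetPartition, path) -> None:
    lines = []
    for base, probes in (
        ("inflammatory", partition.inflammatory),
        ("regulatory", partition.regulatory),
    ):
        if partition.subset_label:
            by_subset: dict[str, list] = {}
            for p in sorted(probes):
                by_subset.setdefault(
                    partition.subset_label.get(p, ""), []
                ).append(p)
            for subset, members in sorted(by_subset.items()):
                name = f"{base}|{subset}" if subset else base
                lines.append("\t".join([name, "na", *members]))
        else:
            lines.append("\t".join([base, "na", *sorted(probes)]))
    Path(path).write_text("\n".join(lines) + "\n")


# --- subjects --------------------------------------------------------------

SUBJECT_COLUMNS = [
    "subject_id", "pre_sample_id", "post_sample_id", "sex", "age",
    "hla_risk", "autoantibody_count", "adherence",
]


def read_subjects_csv(path) -> list:
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise CoinflamError(f"subject table missing columns: {sorted(missing)}")
    return [
        SubjectVisitPair(
            subject_id=str(r.subject_id),
            pre_sample_id=str(r.pre_sample_id),
            post_sample_id=str(r.post_sample_id),
            sex=str(r.sex),
            age=float(r.age),
            hla_risk=str(r.hla_risk),
            autoantibody_count=int(r.autoantibody_count),
            adherence=float(r.adherence),
        )
        for r in df.itertuples()
    ]


def write_subjects_csv(pairs, path) -> None:
    pd.DataFrame([vars(p) for p in pairs])[SUBJECT_COLUMNS].to_csv(
        path, index=False
    )


# --- OTU tables ------------------------------------------------------------

def read_otu_tsv(path) -> OtuCountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "lineage" not in df.columns:
        raise CoinflamError("OTU TSV must end with a 'lineage' column")
    df = df.rename_axis(None)
    lineages = df["lineage"].astype(str)
    counts = df.drop(columns="lineage").T  # stored OTUs x samples
    return OtuCountTable(counts, lineages)


def write_otu_tsv(table: OtuCountTable, path) -> None:
    out = table.counts.T.copy()  # OTUs x samples
    out["lineage"] = table.lineages
    out.rename_axis("otu_id").to_csv(path, sep="\t")


# --- analyte panels / covariates ------------------------------------------

def read_analyte_csv(path) -> AnalytePanel:
    return AnalytePanel(pd.read_csv(path))


def write_analyte_csv(panel: AnalytePanel, path) -> None:
    panel.data.to_csv(path, index=False)


# --- distance matrices -----------------------------------------------------

def read_distance_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return df


def write_distance_tsv(dm: pd.DataFrame, path) -> None:
    dm.rename_axis("sample_id").to_csv(path, sep="\t")


# --- signed regulator networks ---------------------------------------------

def read_network_tsv(path) -> dict:
    """Three-column TSV (regulator, target, sign) -> {regulator: network}."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["regulator", "target", "sign"],
        comment="#",
    )
    nets = {}
    for reg, grp in df.groupby("regulator"):
        edges = dict(zip(grp["target"], grp["sign"].astype(int)))
        nets[str(reg)] = SignedRegulatorNetwork(str(reg), edges)
    return nets
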