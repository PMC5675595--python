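"""Nuclear-retention analysis of compartment-resolved expression data.

For each transcript the nuclear/cytoplasmic ratio R = N/C quantifies nuclear
retention; the index I = R_KO / R_WT measures how loss of IRAK2 shifts that
balance (I > 1: the knockout retains the transcript in the nucleus).
LPS-induced transcripts are ranked by I; the top-ranked ones form the
positive set for motif enrichment and the unaffected ones (I near 1) the
negative set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1.0  # pseudocount on the relative-abundance scale


@dataclass
class ExpressionMatrix:
    """Linear-scale abundances (transcripts x samples) plus sample metadata.

    ``metadata`` is indexed by sample_id with columns genotype (WT/KO),
    compartment (nuclear/cytoplasmic), timepoint, replicate.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.metadata.index):
            missing = set(self.values.columns) - set(self.metadata.index)
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("abundances must be >= 0")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate transcript ids")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def samples(self, genotype: str, compartment: str, timepoint: str) -> list[str]:
        md = self.metadata
        mask = (
            (md["genotype"] == genotype)
            & (md["compartment"] == compartment)
            & (md["timepoint"] == timepoint)
        )
        return list(md.index[mask])

    def timepoints(self) -> list[str]:
        return list(pd.unique(self.metadata["timepoint"]))


@dataclass
class GeneSetPartition:
    """Ordered positive set (strongest retention) vs negative set."""

    positive_ids: list[str]
    negative_ids: list[str]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.positive_ids) & set(self.negative_ids):
            raise ValueError("positive and negative sets overlap")


def read_expression(values_source, metadata_source) -> ExpressionMatrix:
    """Read the expression TSV (first column transcript_id) + metadata TSV."""
    values = pd.read_csv(values_source, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_source, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(values, metadata)


def summarize_abundance(
    matrix: ExpressionMatrix,
    genotype: str,
    compartment: str,
    timepoint: str,
    geometric: bool = False,
) -> pd.Series:
    """Per-transcript replicate summary (arithmetic mean by default)."""
    samples = matrix.samples(genotype, compartment, timepoint)
    if not samples:
        raise KeyError(f"no samples for ({genotype}, {compartment}, {timepoint})")
    sub = matrix.values[samples]
    if geometric:
        return np.exp(np.log(sub + 1e-12).mean(axis=1))
    return sub.mean(axis=1)


def call_induced(
    matrix: ExpressionMatrix,
    baseline_timepoint: str,
    lps_timepoint: str,
    genotype: str = "WT",
    fc_threshold: float = 2.0,
    epsilon: float = DEFAULT_EPSILON,
) -> set[str]:
    """Transcripts whose whole-cell abundance rises >= fc_threshold under LPS.

    Whole-cell abundance is the sum of the nuclear and cytoplasmic replicate
    means; a pseudocount stabilizes the fold change at low abundance.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    base = sum(
        summarize_abundance(matrix, genotype, comp, baseline_timepoint)
        for comp in ("nuclear", "cytoplasmic")
    )
    lps = sum(
        summarize_abundance(matrix, genotype, comp, lps_timepoint)
        for comp in ("nuclear", "cytoplasmic")
    )
    fc = (lps + epsilon) / (base + epsilon)
    return set(fc.index[fc >= fc_threshold])


def retention_ratio(N, C, epsilon: float = DEFAULT_EPSILON):
    """Nuclear/cytoplasmic ratio R = (N + eps) / (C + eps)."""
    return (np.asarray(N, dtype=float) + epsilon) / (np.asarray(C, dtype=float) + epsilon)


def retention_index(r_ko, r_wt):
    """Impact of the knockout on retention: I = R_KO / R_WT."""
    r_ko = np.asarray(r_ko, dtype=float)
    r_wt = np.asarray(r_wt, dtype=float)
    if (r_ko <= 0).any() or (r_wt <= 0).any():
        raise ValueError("retention ratios must be positive")
    return r_ko / r_wt


def retention_table(
    matrix: ExpressionMatrix,
    baseline_timepoint: str,
    lps_timepoint: str,
    fc_threshold: float = 2.0,
    epsilon: float = DEFAULT_EPSILON,
    geometric: bool = False,
) -> pd.DataFrame:
    """Per-transcript N/C summaries, ratios, index I, induction call and rank.

    R and I are computed at the chosen LPS timepoint; induction contrasts the
    baseline and LPS timepoints in wild-type whole-cell abundance.  Rank 1 is
    the largest I among induced transcripts (ties by transcript_id).
    """
    cells = {}
    for geno in ("WT", "KO"):
        for comp, tag in (("nuclear", "N"), ("cytoplasmic", "C")):
            cells[f"{tag}_{geno}"] = summarize_abundance(
                matrix, geno, comp, lps_timepoint, geometric=geometric
            )
    table = pd.DataFrame(cells)
    table["R_WT"] = retention_ratio(table["N_WT"], table["C_WT"], epsilon)
    table["R_KO"] = retention_ratio(table["N_KO"], table["C_KO"], epsilon)
    table["I"] = retention_index(table["R_KO"], table["R_WT"])
    induced = call_induced(
        matrix, baseline_timepoint, lps_timepoint,
        fc_threshold=fc_threshold, epsilon=epsilon,
    )
    table["induced"] = table.index.isin(induced)
    table["rank"] = 0
    # deterministic ordering: I descending, ties by transcript_id ascending
    order = sorted(
        table.index[table["induced"]], key=lambda t: (-table.at[t, "I"], t)
    )
    table.loc[order, "rank"] = np.arange(1, len(order) + 1)
    table.index.name = "transcript_id"
    return table


def rank_and_partition(
    table: pd.DataFrame,
    positive_size: int = 70,
    negative_threshold: float = 1.1,
) -> GeneSetPartition:
    """Top ``positive_size`` induced transcripts by I vs the unaffected rest.

    The negative set is every induced transcript outside the positive set
    with I <= negative_threshold (its compartment distribution essentially
    unchanged by the knockout).
    """
    induced = table.loc[table["induced"]]
    if len(induced) < 2:
        raise ValueError(f"need >= 2 induced transcripts, got {len(induced)}")
    order = sorted(induced.index, key=lambda t: (-induced.at[t, "I"], t))
    if len(order) < positive_size:
        logger.warning(
            "only %d induced transcripts; positive set clamped below %d",
            len(order), positive_size,
        )
    positive = order[:positive_size]
    negative = [
        t for t in order[positive_size:] if induced.at[t, "I"] <= negative_threshold
    ]
    return GeneSetPartition(
        positive_ids=positive,
        negative_ids=negative,
        parameters={
            "positive_size": positive_size,
            "negative_threshold": negative_threshold,
            "n_induced": len(order),
        },
    )


def write_partition(partition: GeneSetPartition, tsv_path, pos_path=None, neg_path=None):
    """Write the partition as a TSV and optional plain-text id lists."""
    rows = [
        {"transcript_id": t, "set": "positive", "order": i + 1}
        for i, t in enumerate(partition.positive_ids)
    ] + [
        {"transcript_id": t, "set": "negative", "order": 0}
        for t in partition.negative_ids
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if pos_path is not None:
        with open(pos_path, "w") as fh:
            fh.write("".join(f"{t}\n" for t in partition.positive_ids))
    if neg_path is not None:
        with open(neg_path, "w") as fh:
            fh.write("".join(f"{t}\n" for t in partition.negative_ids))


def read_partition(tsv_source) -> GeneSetPartition:
    df = pd.read_csv(tsv_source, sep="\t", dtype={"transcript_id": str})
    pos = df.loc[df["set"] == "positive"].sort_values("order")["transcript_id"].tolist()
    neg = df.loc[df["set"] == "negative"]["transcript_id"].tolist()
    return GeneSetPartition(pos, neg)
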