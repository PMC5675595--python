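"""RIP-qPCR fold enrichment by percent-input-normalized delta-delta-Ct.

Each immunoprecipitated fraction's Ct is first normalized to the input
fraction, correcting for the share of input RNA saved:

    dCt[normalized RIP] = Ct[RIP] - (Ct[Input] - log2(fraction saved))

then adjusted for the nonspecific (IgG) antibody background:

    ddCt[RIP/NS] = dCt[normalized RIP] - dCt[normalized NS]
    fold enrichment = 2^(-ddCt)

so fold enrichment 1 means no binding above the IgG control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class RipResult:
    target_id: str
    dct_rip: float
    dct_ns: float
    ddct: float
    fold_enrichment: float


def normalized_delta_ct(ct_target: float, ct_input: float, fraction_input_saved: float) -> float:
    """Input-normalized dCt, correcting for the fraction of input saved."""
    if not 0 < fraction_input_saved <= 1:
        raise ValueError(f"fraction_input_saved must be in (0, 1], got {fraction_input_saved}")
    return ct_target - (ct_input - math.log2(fraction_input_saved))


def fold_enrichment(dct_rip: float, dct_ns: float) -> float:
    """2^(-(dct_rip - dct_ns)); shared input terms cancel in the difference."""
    return 2.0 ** (-(dct_rip - dct_ns))


def _mean_ct(raw) -> float:
    """Replicate Cts may arrive as a comma-separated list; average them."""
    if isinstance(raw, str):
        values = [float(v) for v in raw.split(",")]
        return sum(values) / len(values)
    return float(raw)


def analyze_table(table: pd.DataFrame) -> pd.DataFrame:
    """Compute fold enrichment per target from a long-format Ct table.

    Expected columns: target_id, antibody (specific/IgG), ct (scalar or
    comma-separated replicates), ct_input, fraction_input_saved.
    """
    required = {"target_id", "antibody", "ct", "ct_input", "fraction_input_saved"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    results = []
    for target_id, group in table.groupby("target_id", sort=True):
        by_ab = {ab.lower(): row for ab, row in zip(group["antibody"], group.itertuples())}
        if "specific" not in by_ab or "igg" not in by_ab:
            raise ValueError(f"{target_id}: need one 'specific' and one 'IgG' row")
        rip_row, ns_row = by_ab["specific"], by_ab["igg"]
        dct_rip = normalized_delta_ct(
            _mean_ct(rip_row.ct), _mean_ct(rip_row.ct_input),
            float(rip_row.fraction_input_saved),
        )
        dct_ns = normalized_delta_ct(
            _mean_ct(ns_row.ct), _mean_ct(ns_row.ct_input),
            float(ns_row.fraction_input_saved),
        )
        ddct = dct_rip - dct_ns
        results.append(
            RipResult(target_id, dct_rip, dct_ns, ddct, fold_enrichment(dct_rip, dct_ns))
        )
    return pd.DataFrame([r.__dict__ for r in results])


def run_rip(in_path, out_path) -> pd.DataFrame:
    """Read a Ct TSV, compute fold enrichments, write the result TSV."""
    table = pd.read_csv(in_path, sep="\t", dtype={"target_id": str, "antibody": str, "ct": str})
    out = analyze_table(table)
    out.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return out
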