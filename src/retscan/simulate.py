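"""Synthetic data with known planted structure for every pipeline stage.

The generators emulate the statistical shape of a compartment-resolved
LPS-stimulation experiment: transcripts induced by LPS, a subset of them
retained in the nucleus only in the knockout (the planted IRAK2-dependent
targets), 3'UTRs carrying planted RBP motif sites in the positive set, and
RIP-qPCR Ct tables constructed to invert to a known fold enrichment.  All
generators are pure functions of their parameters and a seed, and record
every planted quantity in a :class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gene_models import TranscriptRecord
from .compartment import ExpressionMatrix
from .motif import IUPACMotif, expand_motif

BASES = np.array(list("ACGU"))


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    planted_target_ids: list[str] = field(default_factory=list)
    retention_multiplier: dict[str, float] = field(default_factory=dict)
    induced_ids: list[str] = field(default_factory=list)
    induction_fc: dict[str, float] = field(default_factory=dict)
    motif_positions: dict[str, list] = field(default_factory=dict)
    rip_enrichment: dict[str, float] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _plant_nonoverlapping(rng, utr: list[str], kmers: list[str], k: int) -> list[int]:
    """Overwrite non-overlapping windows of the UTR with the given k-mers."""
    length = len(utr)
    positions: list[int] = []
    attempts = 0
    for kmer in kmers:
        while True:
            attempts += 1
            if attempts > 1000 * len(kmers):
                raise ValueError("3'UTR too short to place requested sites")
            pos = int(rng.integers(0, length - k + 1))
            if all(pos + k <= q or q + k <= pos for q in positions):
                break
        utr[pos : pos + k] = list(kmer)
        positions.append(pos)
    return sorted(positions)


def generate_transcripts(
    n: int,
    motif: IUPACMotif,
    positive_ids: list[str] | None = None,
    mean_utr3_len: int = 300,
    sites_per_positive: int = 4,
    background_rate: float = 0.2,
    utr5_len: int = 50,
    cds_len: int = 300,
    seed: int | None = None,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Random transcripts with motif k-mers planted in positive 3'UTRs.

    Background sequence is i.i.d. uniform; 3'UTR lengths are uniform in
    [0.5, 1.5] x ``mean_utr3_len``.  Positive transcripts receive
    ``sites_per_positive`` non-overlapping k-mers sampled uniformly from the
    motif expansion; every transcript additionally receives Poisson-planted
    sites at ``background_rate`` per kb of 3'UTR (chance matches arise on
    top of both).  Transcript ids are T0001.. with one isoform per gene.
    """
    rng = np.random.default_rng(seed)
    positive_ids = list(positive_ids or [])
    if n < len(positive_ids):
        raise ValueError("n smaller than the positive set")
    kmers = sorted(expand_motif(motif))
    k = len(motif.pattern)

    ids = [f"T{i + 1:04d}" for i in range(n)]
    unknown = set(positive_ids) - set(ids)
    if unknown:
        raise ValueError(f"positive_ids outside T0001..T{n:04d}: {sorted(unknown)}")

    truth = SyntheticTruth(
        seed=seed,
        parameters={
            "n": n,
            "motif": motif.pattern,
            "mean_utr3_len": mean_utr3_len,
            "sites_per_positive": sites_per_positive,
            "background_rate": background_rate,
            "utr5_len": utr5_len,
            "cds_len": cds_len,
        },
    )
    records = []
    for tid in ids:
        utr3_len = int(rng.integers(mean_utr3_len // 2, mean_utr3_len * 3 // 2 + 1))
        if tid in positive_ids and sites_per_positive * k > utr3_len:
            raise ValueError(
                f"{tid}: 3'UTR of {utr3_len} nt too short for "
                f"{sites_per_positive} sites of {k} nt"
            )
        utr3 = list(_random_sequence(rng, utr3_len))
        n_plant = int(rng.poisson(background_rate * utr3_len / 1000.0))
        if tid in positive_ids:
            n_plant += sites_per_positive
        positions: list[int] = []
        if n_plant:
            chosen = [kmers[j] for j in rng.integers(0, len(kmers), size=n_plant)]
            positions = _plant_nonoverlapping(rng, utr3, chosen, k)
        seq = _random_sequence(rng, utr5_len) + _random_sequence(rng, cds_len) + "".join(utr3)
        cds_start, cds_end = utr5_len, utr5_len + cds_len
        records.append(
            TranscriptRecord(tid, tid.replace("T", "G", 1), seq, cds_start, cds_end)
        )
        if positions:
            truth.motif_positions[tid] = [int(cds_end + p) for p in positions]
    return records, truth


def generate_expression(
    n: int,
    targets: list[str] | None = None,
    frac_induced: float = 0.4,
    induction_fc: float = 8.0,
    retention_multiplier: float = 3.0,
    replicates: int = 3,
    log2_noise_sd: float = 0.3,
    baseline_mean_log2: float = 7.0,
    baseline_sd_log2: float = 1.0,
    nuclear_share: float = 0.3,
    transcript_ids: list[str] | None = None,
    baseline_timepoint: str = "0h",
    lps_timepoint: str = "LPS_6h",
    seed: int | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Compartment-resolved expression with planted induction and retention.

    Baseline whole-cell abundance is log-normal; LPS multiplies induced
    transcripts' totals by ``induction_fc``.  All transcripts split
    nuclear:cytoplasmic at ``nuclear_share`` except planted targets under
    KO + LPS, whose nuclear odds are scaled so R_KO/R_WT equals
    ``retention_multiplier`` exactly in the noiseless construction.
    Multiplicative log-normal noise (sd on the log2 scale) is applied per
    replicate.
    """
    if min(frac_induced, induction_fc, retention_multiplier, replicates) <= 0:
        raise ValueError("generator parameters must be positive")
    rng = np.random.default_rng(seed)
    ids = list(transcript_ids) if transcript_ids is not None else [
        f"T{i + 1:04d}" for i in range(n)
    ]
    if len(ids) != n:
        raise ValueError("transcript_ids length != n")
    targets = list(targets or [])
    if set(targets) - set(ids):
        raise ValueError("targets outside transcript ids")

    n_induced = max(len(targets), int(round(frac_induced * n)))
    non_targets = [t for t in ids if t not in targets]
    extra = list(rng.permutation(non_targets))[: n_induced - len(targets)]
    induced = sorted(set(targets) | set(extra))

    p0 = nuclear_share
    m = retention_multiplier
    share_ko = p0 * m / (p0 * m + (1 - p0))  # odds-scale: R_KO/R_WT = m exactly
    if share_ko >= 1.0:
        raise ValueError("retention multiplier drives nuclear share to >= 1")

    baseline = 2.0 ** rng.normal(baseline_mean_log2, baseline_sd_log2, size=n)
    induced_mask = np.isin(ids, induced)
    target_mask = np.isin(ids, targets)

    columns, names, meta = [], [], []
    for geno in ("WT", "KO"):
        for tp in (baseline_timepoint, lps_timepoint):
            total = baseline * np.where((tp == lps_timepoint) & induced_mask, induction_fc, 1.0)
            share = np.full(n, p0)
            if geno == "KO" and tp == lps_timepoint:
                share[target_mask] = share_ko
            for comp, frac in (("nuclear", share), ("cytoplasmic", 1.0 - share)):
                clean = total * frac
                for rep in range(1, replicates + 1):
                    noise = 2.0 ** rng.normal(0.0, log2_noise_sd, size=n)
                    columns.append(clean * noise)
                    sid = f"{geno}_{comp}_{tp}_r{rep}"
                    names.append(sid)
                    meta.append(
                        {"sample_id": sid, "genotype": geno, "compartment": comp,
                         "timepoint": tp, "replicate": str(rep)}
                    )

    values = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(ids, name="transcript_id"), columns=names
    )
    metadata = pd.DataFrame(meta).set_index("sample_id")
    truth = SyntheticTruth(
        planted_target_ids=list(targets),
        retention_multiplier={t: retention_multiplier for t in targets},
        induced_ids=induced,
        induction_fc={t: induction_fc for t in induced},
        seed=seed,
        parameters={
            "n": n, "frac_induced": frac_induced, "induction_fc": induction_fc,
            "retention_multiplier": retention_multiplier, "replicates": replicates,
            "log2_noise_sd": log2_noise_sd, "nuclear_share": nuclear_share,
            "baseline_timepoint": baseline_timepoint, "lps_timepoint": lps_timepoint,
        },
    )
    return ExpressionMatrix(values, metadata), truth


def generate_rip_table(
    targets: list[str],
    true_enrichment: dict[str, float] | float,
    ct_noise_sd: float = 0.2,
    ct_input: float = 22.0,
    fraction_input_saved: float = 0.1,
    dct_ns: float = 6.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Ct tables that invert to a known fold enrichment.

    Noiseless Cts are constructed so the ddCt pipeline returns exactly the
    requested enrichment; Gaussian noise (sd in cycles) is then added to
    every measured Ct.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(true_enrichment, dict):
        true_enrichment = {t: float(true_enrichment) for t in targets}
    rows = []
    for target in targets:
        e = true_enrichment[target]
        if e <= 0:
            raise ValueError(f"{target}: enrichment must be positive")
        input_term = ct_input - np.log2(fraction_input_saved)
        ct_ns = dct_ns + input_term
        ct_rip = (dct_ns - np.log2(e)) + input_term
        rows.append({
            "target_id": target, "antibody": "specific",
            "ct": float(ct_rip + rng.normal(0, ct_noise_sd)),
            "ct_input": float(ct_input + rng.normal(0, ct_noise_sd)),
            "fraction_input_saved": fraction_input_saved,
        })
        rows.append({
            "target_id": target, "antibody": "IgG",
            "ct": float(ct_ns + rng.normal(0, ct_noise_sd)),
            "ct_input": rows[-1]["ct_input"],  # input fraction shared
            "fraction_input_saved": fraction_input_saved,
        })
    truth = SyntheticTruth(
        rip_enrichment=dict(true_enrichment),
        seed=seed,
        parameters={"ct_noise_sd": ct_noise_sd, "ct_input": ct_input,
                    "fraction_input_saved": fraction_input_saved, "dct_ns": dct_ns},
    )
    return pd.DataFrame(rows), truth


def write_fasta(records: list[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def write_annotation(records: list[TranscriptRecord], path) -> None:
    pd.DataFrame(
        [{"transcript_id": r.transcript_id, "gene_id": r.gene_id,
          "cds_start": r.cds_start, "cds_end": r.cds_end} for r in records]
    ).to_csv(path, sep="\t", index=False)


def write_expression(matrix: ExpressionMatrix, values_path, metadata_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", float_format="%.6f")
    matrix.metadata.to_csv(metadata_path, sep="\t")
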