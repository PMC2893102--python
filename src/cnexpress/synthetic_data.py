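"""Synthetic cohorts with segmental copy-number aberrations, dosage-driven
expression, case/control shifts and proportional-hazards survival.

The generator emulates the statistical structure the integrative analysis
assumes — not any real array platform:

* a genome layout of SNP positions and transcript intervals, constructed so
  that every transcript-mapping rule (overlap with >= 5 SNPs, closest-5
  within the window, 1-4 SNPs in the window, and no SNP within the window)
  is exercised;
* per-sample piecewise-constant copy-number profiles: segment boundaries
  from a Poisson process along each chromosome, segment levels from a fixed
  categorical distribution spanning high-level deletion through high-level
  amplification, and multiplicative log-normal measurement noise;
* expression in which a configurable fraction of transcripts is
  dosage-responsive: log2 expression = baseline + beta * log2(CN ratio) +
  Gaussian noise;
* an independent case/control cohort with differential expression on a
  designated transcript set and survival times from a proportional-hazards
  model whose log-hazard is linear in designated transcripts' (standardized)
  expression plus AJCC stage, with independent exponential censoring.

Every simulated quantity is recorded in a :class:`TruthTable` so that
parameter-recovery tests can compare downstream estimates against the
generating values. All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copy_number import CopyNumberProfile
from .expression_prep import ExpressionMatrix
from .transcript_mapping import TranscriptCN

__all__ = [
    "GenomeLayout",
    "TruthTable",
    "simulate_layout",
    "simulate_copy_number",
    "simulate_expression",
    "simulate_clinical",
    "SEGMENT_LEVELS",
    "SEGMENT_LEVEL_PROBS",
]

#: Segment copy-number-ratio levels spanning all six dose-response bins
#: (<0.5, 0.5-0.93, 0.93-1.07, 1.07-2, 2-4, >4), and their frequencies.
#: The neutral weight puts the expected genome-altered fraction near 0.5,
#: the middle of the 25.6-73.9% burden range typical of node-metastatic
#: tumor genomes.
SEGMENT_LEVELS = (0.3, 0.7, 1.0, 1.5, 3.0, 4.5)
SEGMENT_LEVEL_PROBS = (0.05, 0.15, 0.5, 0.2, 0.07, 0.03)

WINDOW_BP = 250_000


@dataclass
class GenomeLayout:
    """Chromosome sizes, SNP positions and transcript intervals.

    ``snps``: columns (snp_id, chrom, pos), sorted by (chrom, pos), positions
    strictly increasing per chromosome, 0-based.  ``transcripts``: columns
    (transcript_id, chrom, start, end, unique_alignment), 0-based half-open.
    """

    chromosomes: list  # [(name, length_bp)]
    snps: pd.DataFrame
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, grp in self.snps.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")
            if pos.min() < 0 or pos.max() >= lengths[chrom]:
                raise ValueError(f"SNP position outside chromosome {chrom}")
        bad = self.transcripts["start"] >= self.transcripts["end"]
        if bad.any():
            raise ValueError("transcript with start >= end")


@dataclass
class TruthTable:
    """Ground truth recorded by the generators for recovery tests."""

    # per sample: list of (chrom, start, end, true copy-number ratio)
    segment_truth: dict = field(default_factory=dict)
    # per-SNP true (noise-free) ratio matrix, SNPs x samples
    snp_ratio_truth: pd.DataFrame | None = None
    # per transcript: true dosage slope and responsiveness indicator
    dosage_truth: pd.DataFrame | None = None
    # per transcript: true case-vs-control mean shift (testing cohort)
    casecontrol_truth: pd.Series | None = None
    # per transcript: true log-hazard coefficient per standardized unit
    survival_truth: pd.Series | None = None

    def altered_fraction(self, sample: str) -> float:
        """True fraction of SNPs in non-neutral segments for one sample."""
        if self.snp_ratio_truth is None:
            raise ValueError("no per-SNP truth recorded")
        r = self.snp_ratio_truth[sample]
        return float(np.mean(r != 1.0))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_layout(
    n_chrom: int,
    n_snps: int,
    n_transcripts: int,
    seed: int,
    chrom_length_bp: int = 60_000_000,
    transcript_length_bp: tuple[int, int] = (2_000, 120_000),
) -> GenomeLayout:
    """Random genome layout covering every transcript-mapping regime.

    Chromosome 1 carries a structured tail: an isolated cluster of three
    SNPs beyond a >1 Mb SNP desert, plus a region with no SNP within 250 kb.
    Three guarantee transcripts are pinned there (one overlapping >= 5 SNPs,
    one seeing only the 3-SNP cluster within its window, one seeing no SNP
    at all); the remaining transcripts are placed at random, most anchored
    on SNP runs so that the dense overlap rule dominates, as it does on real
    arrays.
    """
    if n_chrom < 1 or n_snps < 1 or n_transcripts < 1:
        raise ValueError("all counts must be >= 1")
    if n_snps < 12:
        raise ValueError("need at least 12 SNPs to build the guarantee regions")
    if n_transcripts < 3:
        raise ValueError("need at least 3 transcripts to cover all mapping regimes")
    rng_snp, rng_tr = _rngs(seed, 2)

    main_span = chrom_length_bp
    tail = 4_000_000  # desert + isolated cluster + empty region on chrom 1
    chroms = [(f"chr{i + 1}", chrom_length_bp + (tail if i == 0 else 0)) for i in range(n_chrom)]

    per_chrom = np.full(n_chrom, n_snps // n_chrom)
    per_chrom[: n_snps % n_chrom] += 1
    snp_rows = []
    for i, (name, _length) in enumerate(chroms):
        k = int(per_chrom[i])
        if i == 0:
            k = max(k - 3, 1)
        pos = np.sort(rng_snp.choice(main_span, size=k, replace=False))
        for p in pos:
            snp_rows.append((name, int(p)))
    # isolated 3-SNP cluster on chrom 1, >1 Mb beyond the last main-block SNP
    iso = [main_span + 1_200_000, main_span + 1_220_000, main_span + 1_240_000]
    for p in iso:
        snp_rows.append((chroms[0][0], int(p)))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos"])
    snps = snps.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    snps.insert(0, "snp_id", [f"snp{i:06d}" for i in range(len(snps))])

    chr1 = chroms[0][0]
    chr1_main = np.sort(
        snps.loc[(snps["chrom"] == chr1) & (snps["pos"] < main_span), "pos"].to_numpy()
    )
    tr_rows = []
    # guarantee 1: overlaps >= 5 SNPs
    lo, hi = int(chr1_main[0]), int(chr1_main[min(6, len(chr1_main) - 1)])
    tr_rows.append((chr1, max(lo - 50, 0), hi + 50))
    # guarantee 2: no overlap, only the 3 isolated SNPs within 250 kb
    tr_rows.append((chr1, iso[2] + 100_000, iso[2] + 110_000))
    # guarantee 3: no SNP within 250 kb
    tr_rows.append((chr1, iso[2] + 600_000, iso[2] + 620_000))

    lmin, lmax = transcript_length_bp
    snps_by_chrom = {c: grp["pos"].to_numpy() for c, grp in snps.groupby("chrom")}
    for _ in range(n_transcripts - 3):
        name, length = chroms[rng_tr.integers(n_chrom)]
        tlen = int(rng_tr.integers(lmin, lmax + 1))
        pos = snps_by_chrom[name]
        if rng_tr.random() < 0.8 and len(pos) >= 5:
            # anchor on a run of 5 SNPs so the overlap rule fires
            i0 = int(rng_tr.integers(0, max(len(pos) - 4, 1)))
            start = max(int(pos[i0]) - 100, 0)
            end = max(int(pos[min(i0 + 4, len(pos) - 1)]) + 100, start + tlen)
        else:
            start = int(rng_tr.integers(0, max(length - tlen, 1)))
            end = start + tlen
        tr_rows.append((name, start, min(end, length - 1)))
    transcripts = pd.DataFrame(tr_rows, columns=["chrom", "start", "end"])
    transcripts.insert(0, "transcript_id", [f"t{i:05d}" for i in range(len(transcripts))])
    transcripts["unique_alignment"] = True
    return GenomeLayout(chromosomes=chroms, snps=snps, transcripts=transcripts)


def simulate_copy_number(
    layout: GenomeLayout,
    n_samples: int,
    segment_rate: float = 0.2,
    noise_sd: float = 0.15,
    seed: int = 0,
    levels: tuple = SEGMENT_LEVELS,
    level_probs: tuple = SEGMENT_LEVEL_PROBS,
) -> tuple[CopyNumberProfile, TruthTable]:
    """Piecewise-constant copy-number profiles with log-normal noise.

    Segment boundaries are a Poisson process with ``segment_rate`` expected
    breakpoints per Mb; each segment's true ratio is drawn from
    ``levels``/``level_probs``; the observed per-SNP ratio is the segment
    ratio times 2**N(0, noise_sd) (noise_sd on the log2 scale).
    """
    if len(layout.snps) == 0:
        raise ValueError("layout has no SNPs")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng_seg, rng_noise = _rngs(seed, 2)
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    snps = layout.snps
    truth = TruthTable()
    true_ratio = np.empty((len(snps), n_samples))

    for j, sid in enumerate(sample_ids):
        segments = []
        for chrom, length in layout.chromosomes:
            n_bp = rng_seg.poisson(segment_rate * length / 1e6)
            breaks = np.sort(rng_seg.integers(1, length, size=n_bp))
            bounds = np.concatenate(([0], breaks, [length]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b <= a:
                    continue
                level = float(rng_seg.choice(levels, p=level_probs))
                segments.append((chrom, int(a), int(b), level))
        truth.segment_truth[sid] = segments
        seg_df = pd.DataFrame(segments, columns=["chrom", "start", "end", "ratio"])
        for chrom, grp in seg_df.groupby("chrom", sort=False):
            mask = snps["chrom"].values == chrom
            pos = snps["pos"].values[mask]
            idx = np.searchsorted(grp["end"].values, pos, side="right")
            true_ratio[mask, j] = grp["ratio"].values[np.minimum(idx, len(grp) - 1)]

    noise = rng_noise.normal(0.0, noise_sd, size=true_ratio.shape) if noise_sd > 0 else 0.0
    observed = true_ratio * (2.0**noise)
    log2r = pd.DataFrame(np.log2(observed), index=snps["snp_id"].values, columns=sample_ids)
    log2r.index.name = "snp_id"
    truth.snp_ratio_truth = pd.DataFrame(
        true_ratio, index=snps["snp_id"].values, columns=sample_ids
    )
    profile = CopyNumberProfile(snps=snps, log2_ratios=log2r)
    return profile, truth


def simulate_expression(
    layout: GenomeLayout,
    truth: TruthTable,
    transcript_cn: TranscriptCN,
    dosage_fraction: float = 0.3,
    beta_mean: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    beta_sd: float = 0.0,
    baseline_range: tuple[float, float] = (5.0, 10.0),
) -> ExpressionMatrix:
    """Dosage-driven log2 expression over the discovery cohort.

    A fraction ``dosage_fraction`` of the mapped transcripts is
    dosage-responsive with slope beta ~ N(beta_mean, beta_sd) (degenerate at
    beta_mean by default); their log2 expression is baseline +
    beta * log2(true transcript copy-number ratio) + N(0, noise_sd). The
    remaining transcripts have beta = 0. ``truth.dosage_truth`` is filled.
    """
    if not (0.0 <= dosage_fraction <= 1.0):
        raise ValueError("dosage_fraction must be in [0, 1]")
    ids = list(layout.transcripts["transcript_id"])
    if set(transcript_cn.meta["transcript_id"]) != set(ids):
        raise ValueError("transcript sets of layout and transcript_cn differ")
    rng_pick, rng_base, rng_noise = _rngs(seed, 3)
    mapped = transcript_cn.meta.loc[
        transcript_cn.meta["rule"] != "unmapped", "transcript_id"
    ].tolist()
    n_resp = int(round(dosage_fraction * len(mapped)))
    responsive = set(rng_pick.choice(mapped, size=n_resp, replace=False)) if n_resp else set()

    samples = transcript_cn.values.columns
    baseline = rng_base.uniform(*baseline_range, size=len(ids))
    betas = np.zeros(len(ids))
    expr = np.empty((len(ids), len(samples)))
    cn = transcript_cn.values
    for i, tid in enumerate(ids):
        if tid in responsive:
            betas[i] = rng_pick.normal(beta_mean, beta_sd) if beta_sd > 0 else beta_mean
        x = np.zeros(len(samples))
        if tid in cn.index:
            v = cn.loc[tid].to_numpy(dtype=float)
            if not np.any(np.isnan(v)):
                x = np.log2(v)
        eps = rng_noise.normal(0.0, noise_sd, size=len(samples)) if noise_sd > 0 else 0.0
        expr[i] = baseline[i] + betas[i] * x + eps
    truth.dosage_truth = pd.DataFrame(
        {"transcript_id": ids, "beta": betas, "responsive": [t in responsive for t in ids]}
    ).set_index("transcript_id")
    values = pd.DataFrame(expr, index=ids, columns=samples)
    values.index.name = "transcript_id"
    return ExpressionMatrix(values=values, normalized=False)


def simulate_clinical(
    n_cases: int,
    n_controls: int,
    transcript_ids,
    risk_transcripts,
    hr_per_unit: float = 2.0,
    censor_rate: float = 0.02,
    seed: int = 0,
    case_shift_transcripts=None,
    case_shift: float = 1.0,
    expr_noise_sd: float = 1.0,
    baseline_range: tuple[float, float] = (5.0, 10.0),
    stage_hr: float = 1.5,
    median_survival_months: float = 24.0,
    nonspecific_death_prob: float = 0.1,
    truth: TruthTable | None = None,
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Independent testing cohort: clinical table plus shifted expression.

    Cases carry a mean log2-expression shift of ``case_shift`` on
    ``case_shift_transcripts`` (default: the risk transcripts). Case survival
    times are exponential under a proportional-hazards model whose log-hazard
    is linear in the standardized expression of ``risk_transcripts`` (log HR
    ``log(hr_per_unit)`` per SD) and in AJCC stage (log HR ``log(stage_hr)``
    per stage unit); censoring is exponential with ``censor_rate`` per month
    (0 means every subject's event is observed). A fraction of deaths is
    relabeled as non-cancer-specific. Ages are uniform on 23-84 and sex is
    Bernoulli(1/2). Controls carry no follow-up. Truth is recorded when a
    :class:`TruthTable` is supplied.
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    if hr_per_unit <= 0:
        raise ValueError("hr_per_unit must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be non-negative")
    ids = list(transcript_ids)
    risk = [t for t in risk_transcripts if t in ids]
    if len(risk) != len(list(risk_transcripts)):
        raise ValueError("risk transcripts must be a subset of the transcript universe")
    shift_set = list(case_shift_transcripts) if case_shift_transcripts is not None else risk
    rng_expr, rng_clin, rng_surv = _rngs(seed, 3)

    n = n_cases + n_controls
    sample_ids = [f"p{i:03d}" for i in range(n)]
    case = np.array([1] * n_cases + [0] * n_controls)
    baseline = rng_expr.uniform(*baseline_range, size=len(ids))
    expr = baseline[:, None] + rng_expr.normal(0.0, expr_noise_sd, size=(len(ids), n))
    shift_idx = [ids.index(t) for t in shift_set]
    for i in shift_idx:
        expr[i, case == 1] += case_shift

    age = rng_clin.uniform(23.0, 84.0, size=n)
    sex = rng_clin.integers(0, 2, size=n)
    stage = np.zeros(n, dtype=int)
    stage[case == 1] = rng_clin.choice([1, 2, 3, 4], p=[0.2, 0.3, 0.3, 0.2], size=n_cases)

    followup = np.full(n, np.nan)
    dead = np.zeros(n, dtype=int)
    oscc_death = np.zeros(n, dtype=int)
    log_hr = np.log(hr_per_unit)
    risk_idx = [ids.index(t) for t in risk]
    case_cols = np.flatnonzero(case == 1)
    lp = np.zeros(n_cases)
    if risk_idx:
        z = expr[np.ix_(risk_idx, case_cols)]
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        lp += log_hr * z.sum(axis=0)
    lp += np.log(stage_hr) * (stage[case_cols] - stage[case_cols].mean())
    h0 = np.log(2.0) / median_survival_months
    t_event = rng_surv.exponential(1.0, size=n_cases) / (h0 * np.exp(lp))
    t_cens = (
        rng_surv.exponential(1.0 / censor_rate, size=n_cases)
        if censor_rate > 0
        else np.full(n_cases, np.inf)
    )
    obs = np.minimum(t_event, t_cens)
    died = (t_event <= t_cens).astype(int)
    specific = (rng_surv.random(n_cases) >= nonspecific_death_prob).astype(int)
    followup[case_cols] = np.round(np.maximum(obs, 0.1), 1)
    dead[case_cols] = died
    oscc_death[case_cols] = died * specific

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "case": case,
            "age": np.round(age, 1),
            "sex": sex,
            "stage": stage,
            "followup_months": followup,
            "dead": dead,
            "oscc_death": oscc_death,
        }
    ).set_index("sample_id")
    values = pd.DataFrame(expr, index=ids, columns=sample_ids)
    values.index.name = "transcript_id"
    if truth is not None:
        truth.casecontrol_truth = pd.Series(
            [case_shift if t in shift_set else 0.0 for t in ids], index=ids
        )
        truth.survival_truth = pd.Series(
            [log_hr if t in risk else 0.0 for t in ids], index=ids
        )
    return clinical, ExpressionMatrix(values=values, normalized=False)
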