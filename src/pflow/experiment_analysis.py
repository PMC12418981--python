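"""Viscosity-rating experiment: design constants, simulation, statistics.

The rating task: observers watch 10-s movies of flowing liquid (the
preprocessed original, or a point-light reconstruction by p-flow or
LK) and rate perceived viscosity on a flexible 101-point slider.  Two
anchor movies fix ratings 10 and 80 at viscosities 0.0035938 and
7.7426 Pa.s; the expected rating of any stimulus is linear in log
viscosity through those anchors.  The measurement set spans 10
viscosities from 0.0020771 to 40.103 Pa.s (log-spaced here, which
lands the expected ratings at 5, 15, ..., 95), presented once per
block over 5 blocks of 10 pseudorandomized trials.

Ratings at a scale extreme expand the scale by 10 in that direction
for the rest of the session; participants who ever used an expanded
scale can be excluded from analysis.

Human data are replaced by a synthetic observer whose rating noise SD
depends on the stimulus algorithm; the analysis pipeline (per-stimulus
mean/SD of the rating error and mean RT over the last 3 blocks, a
one-between/one-within split-plot ANOVA, Tukey post hocs, Bonferroni
across the six ANOVAs) recovers that structure: an algorithm effect on
rating-error SD and RT but none on mean error.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANCHOR_LOW",
    "ANCHOR_HIGH",
    "MEASUREMENT_RANGE",
    "N_BLOCKS",
    "N_STIMULI",
    "TRAINING_BANDS",
    "ABORT_RT",
    "StimulusSpec",
    "RatingScale",
    "TrialRecord",
    "TrainingTrial",
    "SessionRecord",
    "AnovaResult",
    "ObserverModel",
    "expected_rating",
    "measurement_stimuli",
    "apply_scale_expansion",
    "rating_error",
    "moving_window_rms",
    "summarize_participant",
    "mixed_anova",
    "tukey_posthoc",
    "bonferroni_alpha",
    "compute_check_variables",
    "make_design",
    "simulate_observer",
    "simulate_cohort",
    "summarize_cohort",
    "analyze_cohort",
]

#: (viscosity Pa.s, rating) anchors of the rating scale.
ANCHOR_LOW = (0.0035938, 10.0)
ANCHOR_HIGH = (7.7426, 80.0)
#: Viscosity range of the 10-level measurement set (Pa.s).
MEASUREMENT_RANGE = (0.0020771, 40.103)
N_BLOCKS = 5
N_STIMULI = 10
#: Acceptance bands for the two training anchors (rating 10 and 80).
TRAINING_BANDS = {10.0: (6.0, 14.0), 80.0: (76.0, 84.0)}
#: A trial is aborted when the response time reaches this many seconds.
ABORT_RT = 60.0

ALGORITHMS = ("original", "pflow", "lk")


@dataclasses.dataclass(frozen=True)
class StimulusSpec:
    stimulus_id: str
    viscosity: float
    algorithm: str
    expected_rating: float

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")


@dataclasses.dataclass
class RatingScale:
    """The flexible 101-point rating scale with its anchors.

    Bounds only ever widen over a session (see
    :func:`apply_scale_expansion`).
    """

    lower: float = 0.0
    upper: float = 100.0
    anchor_low: tuple[float, float] = ANCHOR_LOW
    anchor_high: tuple[float, float] = ANCHOR_HIGH
    expansion_step: float = 10.0

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("scale lower bound must be below upper bound")

    @property
    def expanded(self) -> bool:
        return self.lower < 0.0 or self.upper > 100.0


@dataclasses.dataclass
class TrialRecord:
    participant_id: str
    block: int
    trial_index: int
    stimulus: StimulusSpec
    actual_rating: float
    rt: float
    aborted: bool = False

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("rt must be > 0")
        if self.aborted != (self.rt >= ABORT_RT):
            raise ValueError("aborted flag must equal (rt >= 60 s)")


@dataclasses.dataclass(frozen=True)
class TrainingTrial:
    target: float  # 10 or 80
    response: float


@dataclasses.dataclass
class SessionRecord:
    """One participant's full session: training, practice, measurement."""

    participant_id: str
    algorithm: str
    training: list[TrainingTrial]
    practice_errors: list[float]
    trials: list[TrialRecord]
    final_scale: RatingScale


@dataclasses.dataclass
class AnovaResult:
    """Split-plot ANOVA table plus optional Tukey post hocs."""

    table: pd.DataFrame  # effect, ss, df1, df2, F, p, eta_sq
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


@dataclasses.dataclass
class ObserverModel:
    """Synthetic observer with algorithm-dependent precision and RT.

    ``actual = clip-to-scale(expected + bias + N(0, sigma))`` where
    sigma depends on the stimulus algorithm; response times are
    log-normal with a per-algorithm location shift.  Defaults encode a
    precision ordering original < pflow < lk (and a slower lk), the
    structure the analysis pipeline is meant to recover.
    """

    bias: float = 0.0
    sigma_by_algorithm: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"original": 6.0, "pflow": 8.0, "lk": 11.0})
    rt_location: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"original": math.log(8.0),
                                 "pflow": math.log(8.0),
                                 "lk": math.log(10.0)})
    rt_scale: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_by_algorithm.values()):
            raise ValueError("rating-noise SDs must be > 0")


# ---------------------------------------------------------------------------
# scale machinery

def expected_rating(viscosity: float, scale: RatingScale | None = None) -> float:
    """Expected rating of a viscosity: linear in log viscosity.

    The line passes through the two anchors (rating 10 at the
    low-viscosity anchor, 80 at the high one) and is extrapolated
    beyond them — the measurement set exceeds the anchor range.
    """
    scale = scale or RatingScale()
    if viscosity <= 0:
        raise ValueError("viscosity must be > 0")
    (v_lo, r_lo), (v_hi, r_hi) = scale.anchor_low, scale.anchor_high
    frac = (math.log(viscosity) - math.log(v_lo)) / (math.log(v_hi) - math.log(v_lo))
    return r_lo + (r_hi - r_lo) * frac


def measurement_stimuli(algorithm: str = "pflow",
                        scale: RatingScale | None = None) -> list[StimulusSpec]:
    """The 10-level measurement set for one algorithm condition."""
    scale = scale or RatingScale()
    viscosities = np.geomspace(*MEASUREMENT_RANGE, N_STIMULI)
    return [
        StimulusSpec(stimulus_id=f"m{i:02d}", viscosity=float(v),
                     algorithm=algorithm,
                     expected_rating=expected_rating(float(v), scale))
        for i, v in enumerate(viscosities)
    ]


def apply_scale_expansion(scale: RatingScale, rating: float) -> RatingScale:
    """Expand the scale by one step when a rating sits at an extreme.

    A rating equal to the current lower (upper) bound widens that bound
    by ``expansion_step``; interior ratings leave the scale unchanged.
    Repeatable without limit.
    """
    if not scale.lower <= rating <= scale.upper:
        raise ValueError(
            f"rating {rating} outside current scale "
            f"[{scale.lower}, {scale.upper}]")
    lower, upper = scale.lower, scale.upper
    if rating == lower:
        lower -= scale.expansion_step
    elif rating == upper:
        upper += scale.expansion_step
    return dataclasses.replace(scale, lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# per-participant analysis

def rating_error(trial: TrialRecord) -> float:
    """Signed rating error: actual minus expected."""
    if trial.aborted:
        raise ValueError("aborted trials carry no rating error")
    return trial.actual_rating - trial.stimulus.expected_rating


def _block_reorder(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Reorder blocks 2..B within-block to block 1's stimulus order."""
    blocks: dict[int, list[TrialRecord]] = {}
    for tr in trials:
        blocks.setdefault(tr.block, []).append(tr)
    block_ids = sorted(blocks)
    first = blocks[block_ids[0]]
    ref_order = [tr.stimulus.stimulus_id for tr in first]
    if len(set(ref_order)) != len(ref_order):
        raise ValueError("first block repeats a stimulus")
    out: list[TrialRecord] = list(first)
    for b in block_ids[1:]:
        by_stim = {tr.stimulus.stimulus_id: tr for tr in blocks[b]}
        if set(by_stim) != set(ref_order) or len(blocks[b]) != len(ref_order):
            raise ValueError(f"block {b} does not contain each stimulus once")
        out.extend(by_stim[s] for s in ref_order)
    return out


def moving_window_rms(trials: Sequence[TrialRecord], w: int = 10) -> np.ndarray:
    """RMS rating error over a moving window of ``w`` trials.

    Trials in every block after the first are first reordered within
    block to match the stimulus order of the first block, so each
    window of ``w = 10`` covers all 10 stimuli exactly once; a 50-trial
    session yields 41 values.
    """
    ordered = _block_reorder(trials)
    errors = np.array([rating_error(tr) for tr in ordered])
    n = len(errors)
    if w < 1 or w > n:
        raise ValueError("window must be in [1, n_trials]")
    sq = errors**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    return np.sqrt((csum[w:] - csum[:-w]) / w)


def summarize_participant(
    trials: Sequence[TrialRecord],
    keep_blocks: Iterable[int] = (3, 4, 5),
) -> pd.DataFrame:
    """Per-stimulus mean/SD of the rating error and mean RT.

    Only the retained blocks are analyzed (by default the final three:
    performance stabilizes after two blocks).  The SD uses the n-1
    denominator; a stimulus with fewer than 2 retained repetitions has
    an undefined SD (NaN) and is flagged.
    """
    keep = set(keep_blocks)
    rows = []
    for tr in trials:
        if tr.block in keep and not tr.aborted:
            rows.append((tr.stimulus.stimulus_id,
                         tr.stimulus.expected_rating,
                         rating_error(tr), tr.rt))
    df = pd.DataFrame(rows, columns=["stimulus_id", "expected", "error", "rt"])
    if df.empty:
        raise ValueError("no analyzable trials in the retained blocks")
    out = df.groupby("stimulus_id").agg(
        expected=("expected", "first"),
        mean_error=("error", "mean"),
        sd_error=("error", lambda e: e.std(ddof=1)),
        mean_rt=("rt", "mean"),
        n=("error", "size"),
    ).reset_index()
    out["sd_defined"] = out["n"] >= 2
    return out


# ---------------------------------------------------------------------------
# statistics

def mixed_anova(
    values: np.ndarray,
    groups: Sequence,
    effect_names: tuple[str, str, str] = ("algorithm", "stimulus",
                                          "algorithm:stimulus"),
) -> AnovaResult:
    """One-between/one-within (split-plot) ANOVA.

    ``values`` is an ``(N, s)`` table: one row per participant, one
    column per within-factor (stimulus) level; ``groups`` assigns each
    participant to a between-factor (algorithm) level.  Effects are
    tested against their split-plot error terms — the between effect
    against subjects-within-groups, the within and interaction effects
    against the within-subject residual — and effect sizes are
    ``eta^2 = SS_effect / SS_total``.
    """
    y = np.asarray(values, dtype=np.float64)
    if y.ndim != 2:
        raise ValueError("values must be an (N, s) table")
    if not np.all(np.isfinite(y)):
        raise ValueError("unbalanced within-factor: table contains missing cells")
    groups = np.asarray(groups)
    N, s = y.shape
    if groups.shape != (N,):
        raise ValueError("groups must have one label per participant row")
    labels, gidx = np.unique(groups, return_inverse=True)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least 2 between-factor levels")
    n_g = np.bincount(gidx)
    if n_g.min() < 2:
        raise ValueError("need at least 2 participants per group")

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    group_mean = np.array([subj_mean[gidx == g].mean() for g in range(a)])
    stim_mean = y.mean(axis=0)
    cell_mean = np.array([y[gidx == g].mean(axis=0) for g in range(a)])  # (a, s)

    ss_total = np.sum((y - grand) ** 2)
    ss_between_subj = s * np.sum((subj_mean - grand) ** 2)
    ss_a = s * np.sum(n_g * (group_mean - grand) ** 2)
    ss_err_b = ss_between_subj - ss_a
    ss_s = N * np.sum((stim_mean - grand) ** 2)
    ss_as = np.sum(
        n_g[:, None] * (cell_mean - group_mean[:, None]
                        - stim_mean[None, :] + grand) ** 2)
    ss_err_w = ss_total - ss_between_subj - ss_s - ss_as

    df_a, df_err_b = a - 1, N - a
    df_s, df_as = s - 1, (a - 1) * (s - 1)
    df_err_w = (N - a) * (s - 1)
    if df_err_b < 1 or df_err_w < 1:
        raise ValueError("singular design: no error degrees of freedom")

    def _row(name, ss, df1, ss_err, df2):
        ms, ms_err = ss / df1, ss_err / df2
        if ss <= 0 or ms_err <= 0:
            f_val, p = 0.0, 1.0
        else:
            f_val = ms / ms_err
            p = float(stats.f.sf(f_val, df1, df2))
        eta = ss / ss_total if ss_total > 0 else 0.0
        return {"effect": name, "ss": ss, "df1": df1, "df2": df2,
                "F": f_val, "p": p, "eta_sq": eta}

    table = pd.DataFrame([
        _row(effect_names[0], ss_a, df_a, ss_err_b, df_err_b),
        _row(effect_names[1], ss_s, df_s, ss_err_w, df_err_w),
        _row(effect_names[2], ss_as, df_as, ss_err_w, df_err_w),
    ])
    table.attrs["ss_total"] = float(ss_total)
    table.attrs["ss_error_between"] = float(ss_err_b)
    table.attrs["ss_error_within"] = float(ss_err_w)
    table.attrs["group_labels"] = list(labels)
    return AnovaResult(table=table)


def tukey_posthoc(
    group_means: Mapping[str, float],
    group_ns: Mapping[str, int],
    ms_error: float,
    df_error: int,
) -> pd.DataFrame:
    """Tukey(-Kramer) pairwise comparisons via the studentized range.

    ``ms_error`` and ``df_error`` come from the ANOVA error term
    appropriate to the factor (for the between factor of a split-plot
    design on subject means: the pooled variance of subject means with
    ``N - a`` degrees of freedom).
    """
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    names = list(group_means)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    k = len(names)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = names[i], names[j]
            diff = group_means[gi] - group_means[gj]
            se = math.sqrt(ms_error / 2 * (1 / group_ns[gi] + 1 / group_ns[gj]))
            q = abs(diff) / se if se > 0 else 0.0
            p = float(stats.studentized_range.sf(q, k, df_error)) if q > 0 else 1.0
            rows.append({"group_a": gi, "group_b": gj, "diff": diff,
                         "q": q, "p_adj": min(p, 1.0)})
    return pd.DataFrame(rows)


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test alpha after Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def compute_check_variables(session: SessionRecord) -> dict:
    """Session-quality check variables.

    Returns the number of aborted measurement trials (RT >= 60 s), the
    number of baseline training trials needed to respond within the
    acceptance bands ([6, 14] for the rating-10 anchor, [76, 84] for
    rating 80), and the RMS rating error over the practice trials.
    """
    n_aborted = sum(1 for tr in session.trials if tr.aborted)
    n_training = len(session.training)
    pr = np.asarray(session.practice_errors, dtype=np.float64)
    practice_rms = float(np.sqrt(np.mean(pr**2))) if pr.size else float("nan")
    return {"n_aborted": n_aborted, "n_training_trials": n_training,
            "practice_rms": practice_rms}


def training_passed(session: SessionRecord) -> bool:
    """Whether the final response to each anchor fell in its band."""
    last: dict[float, float] = {}
    for tt in session.training:
        last[tt.target] = tt.response
    for target, (lo, hi) in TRAINING_BANDS.items():
        if target not in last or not lo <= last[target] <= hi:
            return False
    return True


# ---------------------------------------------------------------------------
# observer simulation

def make_design(stimuli: Sequence[StimulusSpec],
                rng: np.random.Generator,
                n_blocks: int = N_BLOCKS) -> list[StimulusSpec]:
    """Pseudorandom measurement schedule: each block permutes all stimuli."""
    order: list[StimulusSpec] = []
    for _ in range(n_blocks):
        order.extend(rng.permutation(np.array(stimuli, dtype=object)).tolist())
    return order


def _simulate_ratings(
    expected: np.ndarray,
    noise: np.ndarray,
    bias: float,
    scale: RatingScale,
) -> tuple[np.ndarray, RatingScale]:
    """Sequential clip-and-expand rating simulation for one session."""
    actual = np.empty_like(expected)
    cur = scale
    for i in range(len(expected)):
        raw = expected[i] + bias + noise[i]
        r = min(max(raw, cur.lower), cur.upper)
        actual[i] = r
        if r == cur.lower or r == cur.upper:
            cur = apply_scale_expansion(cur, r)
    return actual, cur


def simulate_observer(
    model: ObserverModel,
    design: Sequence[StimulusSpec],
    scale: RatingScale | None = None,
    participant_id: str = "p000",
    rng: np.random.Generator | None = None,
) -> SessionRecord:
    """Simulate one full session (training, practice, measurement).

    Ratings are the expected rating plus bias plus Gaussian noise with
    the algorithm's SD, clipped to the current scale; extreme ratings
    expand the scale for subsequent trials.  RTs are log-normal with
    the algorithm's location.  Deterministic given the rng state.
    """
    scale = scale or RatingScale()
    rng = rng or np.random.default_rng(model.rng_seed)
    algorithm = design[0].algorithm
    sigma = model.sigma_by_algorithm[algorithm]

    # training: repeat each anchor until in band, at most 3 attempts
    training: list[TrainingTrial] = []
    for target in (10.0, 80.0):
        lo, hi = TRAINING_BANDS[target]
        for _ in range(3):
            resp = float(np.clip(target + rng.normal(0, sigma / 3),
                                 scale.lower, scale.upper))
            training.append(TrainingTrial(target=target, response=resp))
            if lo <= resp <= hi:
                break

    practice_errors = [float(rng.normal(model.bias, sigma)) for _ in range(3)]

    expected = np.array([st.expected_rating for st in design])
    noise = rng.normal(0.0, sigma, size=len(design))
    actual, final_scale = _simulate_ratings(expected, noise, model.bias, scale)
    rts = np.exp(rng.normal(model.rt_location[algorithm], model.rt_scale,
                            size=len(design)))
    rts = np.clip(rts, 1e-3, None)

    trials = []
    for i, st in enumerate(design):
        rt = float(rts[i])
        trials.append(TrialRecord(
            participant_id=participant_id,
            block=i // N_STIMULI + 1,
            trial_index=i + 1,
            stimulus=st,
            actual_rating=float(actual[i]),
            rt=rt,
            aborted=rt >= ABORT_RT,
        ))
    return SessionRecord(participant_id=participant_id, algorithm=algorithm,
                         training=training, practice_errors=practice_errors,
                         trials=trials, final_scale=final_scale)


def simulate_cohort(
    model: ObserverModel,
    n_per_group: int,
    algorithms: Sequence[str] = ALGORITHMS,
    scale: RatingScale | None = None,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a between-group cohort; one row per measurement trial.

    Columns: participant, algorithm, block, trial_index, stimulus_id,
    viscosity, expected, actual, rt, aborted, error, scale_expanded.
    """
    scale = scale or RatingScale()
    rng = np.random.default_rng(
        model.rng_seed if rng_seed is None else rng_seed)
    rows = []
    pid = 0
    for alg in algorithms:
        stimuli = measurement_stimuli(alg, scale)
        sigma = model.sigma_by_algorithm[alg]
        loc = model.rt_location[alg]
        for _ in range(n_per_group):
            design = make_design(stimuli, rng)
            expected = np.array([st.expected_rating for st in design])
            noise = rng.normal(0.0, sigma, size=len(design))
            actual, final_scale = _simulate_ratings(expected, noise,
                                                    model.bias, scale)
            rts = np.clip(np.exp(rng.normal(loc, model.rt_scale,
                                            size=len(design))), 1e-3, None)
            name = f"p{pid:04d}"
            for i, st in enumerate(design):
                rows.append((name, alg, i // N_STIMULI + 1, i + 1,
                             st.stimulus_id, st.viscosity, expected[i],
                             actual[i], rts[i], rts[i] >= ABORT_RT,
                             actual[i] - expected[i], final_scale.expanded))
            pid += 1
    return pd.DataFrame(rows, columns=[
        "participant", "algorithm", "block", "trial_index", "stimulus_id",
        "viscosity", "expected", "actual", "rt", "aborted", "error",
        "scale_expanded"])


def summarize_cohort(
    trials: pd.DataFrame,
    keep_blocks: Iterable[int] = (3, 4, 5),
    exclude_expanded: bool = False,
) -> dict[str, pd.DataFrame]:
    """Participant x stimulus tables of the three dependent variables.

    Returns wide tables (participants as rows, stimuli as columns) for
    mean rating error, SD of the rating error, and mean RT, plus the
    per-participant group labels, computed over the retained blocks.
    """
    df = trials[trials["block"].isin(set(keep_blocks)) & ~trials["aborted"]]
    if exclude_expanded:
        df = df[~df["scale_expanded"]]
    piv = lambda vals, fn: vals.pivot_table(  # noqa: E731
        index="participant", columns="stimulus_id", values=fn[0], aggfunc=fn[1])
    mean_err = piv(df, ("error", "mean"))
    sd_err = df.pivot_table(index="participant", columns="stimulus_id",
                            values="error", aggfunc=lambda e: e.std(ddof=1))
    mean_rt = piv(df, ("rt", "mean"))
    groups = df.groupby("participant")["algorithm"].first().loc[mean_err.index]
    return {"mean_error": mean_err, "sd_error": sd_err, "mean_rt": mean_rt,
            "groups": groups}


def analyze_cohort(
    trials: pd.DataFrame,
    n_tests: int = 6,
    family_alpha: float = 0.05,
    exclude_expanded: bool = False,
) -> dict[str, AnovaResult]:
    """Run the three dependent-variable ANOVAs with Tukey post hocs.

    Each dependent variable (mean rating error, SD of rating error,
    mean RT per stimulus) gets a split-plot ANOVA with algorithm as the
    between factor and stimulus as the within factor; the corrected
    alpha (0.05 / 6 by default, for the three dependent and three check
    variables) is attached to every result.  Tukey comparisons of the
    algorithm groups use subject means against the pooled
    between-subject error.
    """
    tabs = summarize_cohort(trials, exclude_expanded=exclude_expanded)
    groups = tabs["groups"]
    alpha = bonferroni_alpha(n_tests, family_alpha)
    out: dict[str, AnovaResult] = {}
    for dv in ("mean_error", "sd_error", "mean_rt"):
        wide = tabs[dv]
        res = mixed_anova(wide.to_numpy(), groups.to_numpy())
        subj = wide.mean(axis=1)
        by_group = subj.groupby(groups)
        means = by_group.mean().to_dict()
        ns = by_group.size().to_dict()
        pooled = float(np.sum([(v - means[g]) ** 2
                               for v, g in zip(subj, groups)]))
        df_err = len(subj) - len(means)
        ms = pooled / df_err if df_err > 0 else 0.0
        if df_err >= 1 and ms > 0:
            res.posthoc = tukey_posthoc(means, ns, ms, df_err)
        res.alpha = alpha
        out[dv] = res
    return out
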