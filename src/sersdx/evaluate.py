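"""The repeated-split validation protocol and its metrics.

One protocol iteration: draw 80% of the subjects of each group into a
training sample (the rest test), pick the PLS component count by k-fold
(k = 7) subject-grouped cross-validation on the training sample only,
fit, then score every training and test spectrum.  The split is
repeated (30 iterations by default) and specificity, sensitivity,
accuracy and ROC AUC are aggregated as mean / min / max per subsample —
the shape of a classical diagnostic-performance table.

Metrics are per spectrum: each replicate counts separately (an optional
subject-level majority vote is available but not the default).
Sensitivity is recall on Target, specificity recall on Control; AUC is
the Mann–Whitney probability that a Target spectrum outscores a Control
spectrum, ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import CONTROL, TARGET, SpectralDataset
from .errors import DataError, MetricError, ParameterError
from .plsda import (
    DECISION_THRESHOLD,
    VIPProfile,
    fit_pls,
    predict,
    select_components,
    vip,
)

__all__ = [
    "SplitPlan",
    "ProtocolResult",
    "BandReport",
    "split_subjects",
    "confusion_metrics",
    "roc_auc",
    "run_protocol",
    "single_band_accuracy",
    "band_report",
]

METRICS = ("specificity", "sensitivity", "accuracy", "auc")


def _iter_seed(base_seed: int, iteration: int, stage: int) -> np.random.SeedSequence:
    """Deterministic per-iteration, per-stage randomness stream."""
    return np.random.SeedSequence([int(base_seed), int(iteration), int(stage)])


@dataclass
class SplitPlan:
    """Subject-level train/test partition for one protocol iteration."""

    iteration: int
    train_subjects: tuple
    test_subjects: tuple
    seed: int


def split_subjects(
    ds: SpectralDataset,
    train_frac: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
    iteration: int = 0,
) -> SplitPlan:
    """Draw floor(train_frac * n) subjects of each group into training.

    All of a subject's replicate spectra follow its assignment; the draw
    is uniform within group and deterministic given ``seed``.
    """
    subj = ds.subjects()
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for grp in (TARGET, CONTROL):
        members = subj.loc[subj["group"] == grp, "subject_id"].tolist()
        if len(members) < 2:
            raise DataError(f"group {grp!r} has {len(members)} subject(s); need >= 2")
        n_train = int(np.floor(train_frac * len(members)))
        perm = rng.permutation(len(members))
        train += [members[i] for i in perm[:n_train]]
        test += [members[i] for i in perm[n_train:]]
    seed_int = int(seed) if isinstance(seed, (int, np.integer)) else -1
    return SplitPlan(
        iteration=iteration,
        train_subjects=tuple(train),
        test_subjects=tuple(test),
        seed=seed_int,
    )


def confusion_metrics(truth: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """Sensitivity (Target recall), specificity (Control recall), accuracy."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if len(truth) != len(predicted):
        raise DataError("truth and prediction vectors differ in length")
    is_t = truth == TARGET
    is_c = truth == CONTROL
    if not (is_t.any() and is_c.any()):
        raise MetricError("both classes must be present in the truth vector")
    tp = int(np.sum(is_t & (predicted == TARGET)))
    tn = int(np.sum(is_c & (predicted == CONTROL)))
    return {
        "sensitivity": tp / int(is_t.sum()),
        "specificity": tn / int(is_c.sum()),
        "accuracy": (tp + tn) / len(truth),
    }


def roc_auc(truth: np.ndarray, score: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_Target > score_Control) + 0.5 P(tie)."""
    truth = np.asarray(truth, dtype=object)
    score = np.asarray(score, dtype=float)
    is_t = truth == TARGET
    is_c = truth == CONTROL
    n_t, n_c = int(is_t.sum()), int(is_c.sum())
    if n_t == 0 or n_c == 0:
        raise MetricError("both classes must be present to compute AUC")
    ranks = rankdata(score)  # midranks give ties the half weight
    u = ranks[is_t].sum() - n_t * (n_t + 1) / 2.0
    return float(u / (n_t * n_c))


@dataclass
class ProtocolResult:
    """Per-iteration metrics table plus mean/min/max aggregation."""

    per_iteration: pd.DataFrame  # columns: iteration, subsample, 4 metrics
    chosen_A: list[int]
    mean_vip: VIPProfile | None = None
    aggregate: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.aggregate = self.aggregate_from_table()

    def aggregate_from_table(self) -> pd.DataFrame:
        g = self.per_iteration.groupby("subsample")[list(METRICS)]
        agg = g.agg(["mean", "min", "max"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        return agg


def _metrics_row(truth: np.ndarray, score: np.ndarray, label: np.ndarray) -> dict:
    row = confusion_metrics(truth, label)
    row["auc"] = roc_auc(truth, score)
    return row


def _subject_vote(
    subject_id: np.ndarray, truth: np.ndarray, score: np.ndarray, label: np.ndarray
):
    """Collapse replicate spectra to one majority-vote row per subject."""
    df = pd.DataFrame(
        {"sid": subject_id, "truth": truth, "score": score, "target": label == TARGET}
    )
    g = df.groupby("sid", sort=True).agg(
        truth=("truth", "first"), score=("score", "mean"), frac=("target", "mean")
    )
    lab = np.where(
        (g["frac"] > 0.5) | ((g["frac"] == 0.5) & (g["score"] >= DECISION_THRESHOLD)),
        TARGET,
        CONTROL,
    ).astype(object)
    return g["truth"].to_numpy(dtype=object), g["score"].to_numpy(), lab


def run_protocol(
    ds: SpectralDataset,
    n_iterations: int = 30,
    k: int = 7,
    grid: np.ndarray | None = None,
    base_seed: int = 0,
    train_frac: float = 0.8,
    subject_vote: bool = False,
) -> ProtocolResult:
    """Run the full repeated-split protocol on a preprocessed dataset.

    All randomness derives from ``(base_seed, iteration)``; test subjects
    never enter fitting or component selection.  The returned result
    carries the across-iteration mean VIP profile for band reporting.
    """
    records = []
    chosen: list[int] = []
    vip_sum = np.zeros(ds.n_channels)
    for it in range(n_iterations):
        plan = split_subjects(ds, train_frac, seed=_iter_seed(base_seed, it, 0), iteration=it)
        tr_mask = np.isin(ds.subject_id, plan.train_subjects)
        train, test = ds.subset(tr_mask), ds.subset(~tr_mask)
        sel = select_components(
            train.intensities,
            train.y(),
            train.subject_id,
            k=k,
            grid=grid,
            seed=_iter_seed(base_seed, it, 1),
        )
        model = fit_pls(train.intensities, train.y(), sel.chosen_A)
        chosen.append(sel.chosen_A)
        vip_sum += vip(model, ds.axis).vip
        for name, part in (("train", train), ("test", test)):
            score, label = predict(model, part.intensities)
            truth = part.group
            if subject_vote:
                truth, score, label = _subject_vote(part.subject_id, truth, score, label)
            try:
                row = _metrics_row(truth, score, label)
            except MetricError as exc:
                raise MetricError(
                    f"iteration {it}, {name} subsample: {exc} "
                    "(a class is missing from this split)"
                ) from exc
            records.append({"iteration": it, "subsample": name, **row})
    table = pd.DataFrame.from_records(
        records, columns=["iteration", "subsample", *METRICS]
    )
    mean_vip = VIPProfile(axis=ds.axis, vip=vip_sum / max(n_iterations, 1))
    return ProtocolResult(per_iteration=table, chosen_A=chosen, mean_vip=mean_vip)


def _best_threshold(feature: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Accuracy-optimal threshold on one feature; returns (threshold, direction).

    direction +1 classifies Target where feature >= threshold, -1 the
    converse.  Candidates are midpoints between consecutive sorted unique
    values plus the extremes; ties resolve to the first candidate scanned
    (deterministic).
    """
    uniq = np.unique(feature)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    best = (-1.0, candidates[0], 1)
    for thr in candidates:
        for direction in (1, -1):
            pred = (direction * (feature - thr) >= 0).astype(float)
            acc = float(np.mean(pred == y))
            if acc > best[0]:
                best = (acc, thr, direction)
    return best[1], best[2]


def single_band_accuracy(
    ds: SpectralDataset,
    center: float,
    halfwidth: float,
    n_iterations: int = 30,
    base_seed: int = 0,
    train_frac: float = 0.8,
) -> float:
    """Mean test accuracy of a one-band threshold classifier.

    The feature is the mean preprocessed intensity over
    ``[center - halfwidth, center + halfwidth]``; the threshold (and its
    direction) is chosen to maximise training accuracy under the same
    repeated subject-level splits as the full protocol, and evaluated on
    test spectra.
    """
    mask = np.abs(ds.axis - center) <= halfwidth
    if not mask.any():
        raise ParameterError(
            f"band {center}+/-{halfwidth} cm^-1 covers no channel of the axis"
        )
    feature = ds.intensities[:, mask].mean(axis=1)
    y = ds.y()
    accs = []
    for it in range(n_iterations):
        plan = split_subjects(ds, train_frac, seed=_iter_seed(base_seed, it, 0), iteration=it)
        tr = np.isin(ds.subject_id, plan.train_subjects)
        thr, direction = _best_threshold(feature[tr], y[tr])
        pred = (direction * (feature[~tr] - thr) >= 0).astype(float)
        accs.append(float(np.mean(pred == y[~tr])))
    return float(np.mean(accs))


@dataclass
class BandReport:
    """Contiguous above-threshold VIP intervals, sorted by position."""

    intervals: list[dict]  # keys: low, high, peak_position, peak_vip
    threshold: float

    def by_height(self) -> list[dict]:
        """Intervals re-sorted by peak VIP, descending (report order)."""
        return sorted(self.intervals, key=lambda b: -b["peak_vip"])

    def top_positions(self, n: int) -> list[float]:
        return [b["peak_position"] for b in self.by_height()[:n]]


def band_report(profile: VIPProfile, threshold: float = 1.0) -> BandReport:
    """Extract discriminative wavenumber intervals from a VIP profile.

    Runs of consecutive channels with VIP >= threshold become intervals,
    each annotated with the position and height of its VIP maximum.  The
    conventional cutoff 1.0 ("greater than average importance") is the
    default.
    """
    if threshold < 0:
        raise ParameterError("VIP threshold must be >= 0")
    above = profile.vip >= threshold
    intervals: list[dict] = []
    i, n = 0, len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        seg = slice(i, j + 1)
        peak = int(np.argmax(profile.vip[seg])) + i
        intervals.append(
            {
                "low": float(profile.axis[i]),
                "high": float(profile.axis[j]),
                "peak_position": float(profile.axis[peak]),
                "peak_vip": float(profile.vip[peak]),
            }
        )
        i = j + 1
    return BandReport(intervals=intervals, threshold=threshold)
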