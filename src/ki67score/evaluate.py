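"""Metrics, cross-validation and automated proliferation scoring.

Classification metrics use the standard definitions — precision =
TP/(TP+FP), recall = TP/(TP+FN) — with the immunopositive class as
positive. A ``convention="swapped"`` flag exposes the variant with the
two denominators interchanged, for auditing against sources that print
the formulas that way; the standard reading is the default and is the
one consistent with the published worked example (confusion matrix
17028/2277/1287/15840 -> 0.93 / 0.88 / 0.91).

The automated proliferation score (APS) of a field is
``100 * TIP / (TIP + TIN)`` with TIP/TIN the immunopositive and
immunonegative nucleus counts, categorized against the reference ranges
used in breast pathology: low (<15%), average (15-30%), high (>30%).
The published ranges leave [15,16) and (30,31] unassigned; the half-open
cover low < 15 <= average <= 30 < high is used so every score has a
category and ordering is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ndf.network import Network, NetworkConfig
from .ndf.train import TrainConfig, classify_patches, train
from .patching import build_folds, crop_patches, patches_to_arrays, SplitPlan
from .seeds import (
    IMMUNONEGATIVE,
    IMMUNOPOSITIVE,
    NUCLEUS_CLASSES,
    SeedDetectionConfig,
    detect_seeds,
)

log = logging.getLogger(__name__)

CATEGORY_LOW = "low"
CATEGORY_AVERAGE = "average"
CATEGORY_HIGH = "high"


@dataclass
class ConfusionMatrix:
    """2x2 tally, rows = actual, columns = predicted, positive =
    immunopositive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    """Precision, recall and their harmonic mean; None marks an
    undefined metric (zero denominator), never reported as 0."""

    precision: float | None
    recall: float | None
    f_score: float | None

    def rounded(self, ndigits: int = 2) -> "MetricsReport":
        r = lambda v: None if v is None else round(v, ndigits)
        return MetricsReport(r(self.precision), r(self.recall), r(self.f_score))


@dataclass
class ProliferationResult:
    """Per-field proliferation outcome: counts, APS percentage, category.
    ``aps`` and ``category`` are None when no nuclei were found."""

    tip: int
    tin: int
    aps: float | None
    category: str | None


def compute_confusion(predicted, actual, positive_label=IMMUNOPOSITIVE) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix from parallel label sequences."""
    predicted, actual = list(predicted), list(actual)
    if len(predicted) != len(actual):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(actual)} truths"
        )
    tp = sum(1 for p, a in zip(predicted, actual) if a == positive_label and p == positive_label)
    fn = sum(1 for p, a in zip(predicted, actual) if a == positive_label and p != positive_label)
    fp = sum(1 for p, a in zip(predicted, actual) if a != positive_label and p == positive_label)
    tn = sum(1 for p, a in zip(predicted, actual) if a != positive_label and p != positive_label)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def compute_metrics(cm: ConfusionMatrix, convention: str = "standard") -> MetricsReport:
    """Precision, recall, F-score from a confusion matrix.

    ``convention="standard"`` (default): precision = TP/(TP+FP),
    recall = TP/(TP+FN). ``convention="swapped"`` interchanges the two
    denominators (audit variant). F is always the harmonic mean of the
    unrounded precision and recall; rounding happens only at display.
    """
    if convention not in ("standard", "swapped"):
        raise ValueError(f"unknown convention {convention!r}")
    p_den = cm.tp + (cm.fp if convention == "standard" else cm.fn)
    r_den = cm.tp + (cm.fn if convention == "standard" else cm.fp)
    precision = cm.tp / p_den if p_den > 0 else None
    recall = cm.tp / r_den if r_den > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f = None
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(precision=precision, recall=recall, f_score=f)


def compute_aps(tip: int, tin: int) -> ProliferationResult:
    """Automated proliferation score from class counts."""
    if tip < 0 or tin < 0:
        raise ValueError("counts must be >= 0")
    if tip + tin == 0:
        log.warning("no nuclei counted: proliferation score undefined")
        return ProliferationResult(tip=tip, tin=tin, aps=None, category=None)
    aps = 100.0 * tip / (tip + tin)
    return ProliferationResult(tip=tip, tin=tin, aps=aps, category=categorize_aps(aps))


def categorize_aps(aps: float) -> str:
    """Reference proliferation category of an APS percentage."""
    if aps < 15.0:
        return CATEGORY_LOW
    if aps <= 30.0:
        return CATEGORY_AVERAGE
    return CATEGORY_HIGH


def category_error(manual_scores, automated_score: float) -> float:
    """Absolute difference between the mean manual proliferation score
    and the automated score, at two decimals."""
    manual = list(manual_scores)
    if not manual:
        raise ValueError("at least one manual score is required")
    return round(abs(float(np.mean(manual)) - float(automated_score)), 2)


def count_regression(automated_counts, manual_counts):
    """OLS of automated on manual nucleus counts (manual on the x axis).

    Returns (slope, intercept, r_squared); ``r_squared`` is None when the
    manual counts have zero variance.
    """
    a = np.asarray(automated_counts, dtype=float)
    m = np.asarray(manual_counts, dtype=float)
    if len(a) != len(m) or len(a) < 3:
        raise ValueError("need >= 3 paired counts")
    if np.ptp(m) == 0:
        log.warning("manual counts constant: R^2 undefined")
        return None, None, None
    if np.ptp(a) == 0:  # no explained variance
        return 0.0, float(a[0]), 0.0
    res = stats.linregress(m, a)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def match_seeds(detected, truth, max_dist: float = 10.0):
    """Greedy nearest matching of detected seeds to ground-truth seeds.

    Pairs each detection with its nearest unmatched truth seed within
    ``max_dist`` pixels, closest pairs first. Returns (matches, recall,
    class_purity): ``matches`` is a list of (detected, truth) pairs,
    recall the matched fraction of truth seeds, purity the fraction of
    matched pairs whose classes agree (None when nothing matched).
    """
    if not truth:
        return [], None, None
    if not detected:
        return [], 0.0, None
    d_pos = np.array([[s.row, s.col] for s in detected], dtype=float)
    t_pos = np.array([[s.row, s.col] for s in truth], dtype=float)
    dist = np.linalg.norm(d_pos[:, None, :] - t_pos[None, :, :], axis=2)
    pairs = sorted(
        ((dist[i, j], i, j) for i in range(len(detected)) for j in range(len(truth))
         if dist[i, j] <= max_dist)
    )
    used_d, used_t, matches = set(), set(), []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matches.append((detected[i], truth[j]))
    recall = len(matches) / len(truth)
    purity = (
        sum(1 for d, t in matches if d.klass == t.klass) / len(matches)
        if matches else None
    )
    return matches, recall, purity


def score_image(
    image: np.ndarray,
    network: Network,
    detector_config: SeedDetectionConfig | None = None,
    patch_size: int = 71,
    boundary: str = "reflect",
    image_id: str = "",
):
    """End-to-end proliferation scoring of one field.

    Detect seed points, crop a patch per seed, classify each patch, count
    the classes and compute the APS. Returns the
    :class:`ProliferationResult` and per-nucleus records
    (row, col, detected class, classified class, posterior).
    """
    detector_config = detector_config or SeedDetectionConfig()
    seeds, _, _ = detect_seeds(image, detector_config)
    if not seeds:
        log.warning("image %s: no nuclei detected; score undefined", image_id or "?")
        return ProliferationResult(tip=0, tin=0, aps=None, category=None), []
    patches = crop_patches(image, seeds, size=patch_size, boundary=boundary, image_id=image_id)
    X, _ = patches_to_arrays(patches)
    labels, probs = classify_patches(X, network)
    class_names = [IMMUNOPOSITIVE, IMMUNONEGATIVE]
    records = [
        {
            "row": p.seed.row,
            "col": p.seed.col,
            "detected_class": p.seed.klass,
            "classified_class": class_names[int(l)],
            "p_immunopositive": float(pr[0]),
        }
        for p, l, pr in zip(patches, labels, probs)
    ]
    tip = int((labels == 0).sum())
    tin = int((labels == 1).sum())
    return compute_aps(tip, tin), records


def cross_validate(
    patches,
    k: int = 5,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    rng_seed: int = 0,
    classifier=None,
):
    """Stratified k-fold cross-validation of the patch classifier.

    For each fold, trains on the other k-1 folds and evaluates on the
    held-out fold. ``classifier`` may supply a stand-in with the
    interface ``fit(X, y) -> predict(X) -> labels`` (used for audits and
    fast tests); otherwise the decision-forest network is trained with
    the given configs. Returns (per-fold MetricsReport list, mean
    MetricsReport, fold assignment lists).
    """
    plan = SplitPlan(k_folds=k, rng_seed=rng_seed)
    folds = build_folds(list(patches), plan)
    reports = []
    for i, test_fold in enumerate(folds):
        train_patches = [p for j, f in enumerate(folds) if j != i for p in f]
        Xtr, ytr = patches_to_arrays(train_patches)
        Xte, yte = patches_to_arrays(test_fold)
        if classifier is not None:
            model = classifier()
            model.fit(Xtr, ytr)
            pred = np.asarray(model.predict(Xte))
        else:
            cfg = train_config or TrainConfig.desk_scale(rng_seed=rng_seed)
            net, _ = train(Xtr, ytr, net_config or NetworkConfig.small(), cfg)
            pred, _ = classify_patches(Xte, net)
        names = np.array(NUCLEUS_CLASSES)
        cm = compute_confusion(names[pred], names[yte])
        reports.append(compute_metrics(cm))
        log.info("fold %d/%d: %s", i + 1, k, reports[-1].rounded())
    mean = MetricsReport(
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f_score=float(np.mean([r.f_score for r in reports])),
    )
    return reports, mean, folds
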