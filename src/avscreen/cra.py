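"""Color relation analysis (CRA): a similarity classifier with a hue-angle decision.

The classifier compares a query pattern ``phi_r`` (6 features) against a bank
of class-labelled training patterns ``phi_c(k)``:

1.  Euclidean distance ED(k) = ||phi_r - phi_c(k)||_2.
2.  Gray grade rho(k) = xi * exp(-xi * ED(k)) — an exponential similarity
    score sharpened by the recognition coefficient xi > 0.
3.  Class-average grades rho_ave for the three degree-of-stenosis classes,
    with rho_min / rho_max their extremes.
4.  An HSV-style transform: the class averages become inverted RGB channels
    r = (rho_max - rho_ave_III) / (rho_max - rho_min)   (and cyclically for
    g with class I, b with class II), from which a hue angle H in [0, 360),
    a saturation S = (gamma - rho_min) / gamma ("confidence index") and a
    value gamma = rho_max are formed.
5.  The hue fraction H_C = H / 360 is compared with the critical decisions
    H_C = 2/3 (Class I, blue 240°), 1/3 (Class II, green 120°) and 1
    (Class III, red 0°/360°) under circular distance.

Two hue-branch conventions are provided.  ``class_centered`` (default)
anchors each class's branch at its own decision angle, so a pattern most
similar to Class I maps into the sector around 240°, Class II around 120°,
Class III around 0°/360°.  ``as_printed`` swaps the Class I and Class II
offsets (120°/240°); it is kept for comparability but is inconsistent with
the critical decisions above.

The training objective is the mean squared error function (MSEF) between the
target decision values T(k) and the realised H_C(k).  Because H_C lives on a
circle (Class III sits at 1 == 0), the default error is the wrapped
difference min(|T - H_C|, 1 - |T - H_C|); the literal difference is available
as ``error_mode="plain"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import DegenerateHueError, DomainError
from .hemodynamics import CRITICAL_HC, DOSClass, FeaturePattern

__all__ = [
    "CLASS_ORDER",
    "TrainingSet",
    "CRAModel",
    "HSVResult",
    "ColorResult",
    "EvaluationResult",
    "euclidean_distance",
    "gray_grade",
    "class_average_grades",
    "hsv_transform",
    "hue_to_hc",
    "circular_distance",
    "classify_pattern",
    "msef",
    "loo_msef_function",
    "loo_msef",
    "evaluate",
]

CLASS_ORDER = (DOSClass.I, DOSClass.II, DOSClass.III)

#: maximum wrapped squared error; charged to degenerate (unclassifiable) patterns
MAX_WRAPPED_SQERR = 0.25

#: tie-break priority when two class means share rho_max (higher wins)
_BRANCH_PRIORITY = {DOSClass.I: 0, DOSClass.II: 1, DOSClass.III: 2}


@dataclass(frozen=True)
class TrainingSet:
    """Class-labelled training patterns (the comparative-pattern matrix)."""

    patterns: tuple

    def __post_init__(self) -> None:
        pats = tuple(self.patterns)
        if not pats:
            raise DomainError("training set must be nonempty")
        for p in pats:
            if p.dos_class is None:
                raise DomainError("every training pattern needs a dos_class label")
        object.__setattr__(self, "patterns", pats)
        for c in CLASS_ORDER:
            if self.class_counts[c] == 0:
                raise DomainError(f"training set has no Class {c.value} patterns")

    @property
    def class_counts(self) -> dict:
        counts = {c: 0 for c in CLASS_ORDER}
        for p in self.patterns:
            counts[p.dos_class] += 1
        return counts

    @property
    def matrix(self) -> np.ndarray:
        """(K, 6) array of training patterns."""
        return np.vstack([p.phi for p in self.patterns])

    @property
    def labels(self) -> list:
        return [p.dos_class for p in self.patterns]

    def __len__(self) -> int:
        return len(self.patterns)


@dataclass(frozen=True)
class CRAModel:
    """A trained CRA classifier: training bank plus decision constants."""

    training: TrainingSet
    xi: float
    hue_branch_convention: str = "class_centered"
    error_mode: str = "wrapped"
    intensity_rescale: bool = False
    critical_HC: Mapping[DOSClass, float] = field(
        default_factory=lambda: dict(CRITICAL_HC)
    )

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise DomainError(f"recognition coefficient xi must be positive, got {self.xi}")
        if self.hue_branch_convention not in ("class_centered", "as_printed"):
            raise DomainError(
                f"unknown hue branch convention {self.hue_branch_convention!r}"
            )
        if self.error_mode not in ("wrapped", "plain"):
            raise DomainError(f"unknown error mode {self.error_mode!r}")


class HSVResult(NamedTuple):
    """(r, g, b, H, S, gamma) plus the selected branch class and a
    low-confidence flag (set when two class means tie for rho_max)."""

    r: float
    g: float
    b: float
    H: float
    S: float
    gamma: float
    branch: DOSClass
    low_confidence: bool


@dataclass(frozen=True)
class ColorResult:
    """Full decision trace for one query pattern."""

    grades_rho: np.ndarray
    rho_ave: Mapping[DOSClass, float]
    rho_min: float
    rho_max: float
    rgb: Optional[tuple] = None
    hue_H: Optional[float] = None
    saturation_S: Optional[float] = None
    value_gamma: Optional[float] = None
    H_C: Optional[float] = None
    predicted_class: Optional[DOSClass] = None
    unclassifiable: bool = False
    low_confidence: bool = False
    subject_id: Optional[str] = None
    true_class: Optional[DOSClass] = None


@dataclass(frozen=True)
class EvaluationResult:
    accuracy: float
    confusion: "np.ndarray"  # 3x3, rows = true class, cols = predicted (I, II, III)
    results: tuple

    def confusion_frame(self):
        import pandas as pd

        names = [c.value for c in CLASS_ORDER]
        return pd.DataFrame(self.confusion, index=names, columns=names)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def euclidean_distance(phi_r, phi_c) -> float:
    """ED = sqrt(sum_i (phi_r_i - phi_c_i)^2) between two 6-vectors."""
    a = np.asarray(phi_r, dtype=float)
    b = np.asarray(phi_c, dtype=float)
    if a.shape != (6,) or b.shape != (6,):
        raise DomainError(f"expected two 6-vectors, got shapes {a.shape}, {b.shape}")
    return float(np.linalg.norm(a - b))


def gray_grade(ED: float, xi: float) -> float:
    """Gray grade rho = xi * exp(-xi * ED), in (0, xi]; decreasing in ED."""
    if xi <= 0:
        raise DomainError(f"xi must be positive, got {xi}")
    if ED < 0:
        raise DomainError(f"ED must be non-negative, got {ED}")
    return xi * math.exp(-xi * ED)


def class_average_grades(grades, labels) -> tuple:
    """Per-class arithmetic means of the gray grades.

    Returns (rho_ave dict over classes, rho_min, rho_max) where rho_min and
    rho_max are the extremes of the three class means.
    """
    g = np.asarray(grades, dtype=float)
    labels = list(labels)
    if len(labels) != g.size:
        raise DomainError("grades and labels must have equal length")
    rho_ave = {}
    for c in CLASS_ORDER:
        members = [v for v, lab in zip(g, labels) if DOSClass(lab) is c]
        if not members:
            raise DomainError(f"no grades for Class {c.value}")
        rho_ave[c] = float(np.mean(members))
    values = [rho_ave[c] for c in CLASS_ORDER]
    return rho_ave, min(values), max(values)


def _hue_branches(convention: str) -> dict:
    # each branch: (channel-difference selector, offset degrees, wrap?)
    if convention == "class_centered":
        return {
            DOSClass.I: ("b-r", 240.0, False),
            DOSClass.II: ("r-g", 120.0, False),
            DOSClass.III: ("g-b", 360.0, True),
        }
    if convention == "as_printed":
        return {
            DOSClass.I: ("b-r", 120.0, False),
            DOSClass.II: ("r-g", 240.0, False),
            DOSClass.III: ("g-b", 360.0, True),
        }
    raise DomainError(f"unknown hue branch convention {convention!r}")


def hsv_transform(rho_ave, convention: str = "class_centered") -> HSVResult:
    """Map the three class-average grades to (r, g, b, H, S, gamma).

    ``rho_ave`` is a mapping DOSClass -> mean grade or a (I, II, III) triple.
    The channels are Delta-rho-normalised, so exactly one equals 0 and one
    equals 1; the hue branch is selected by which class mean attains rho_max
    and the hue offset by ``convention``.  Degenerate input
    (rho_min == rho_max) raises :class:`DegenerateHueError`.
    """
    if isinstance(rho_ave, Mapping):
        means = {DOSClass(c): float(rho_ave[c]) for c in rho_ave}
    else:
        triple = tuple(rho_ave)
        if len(triple) != 3:
            raise DomainError("rho_ave must have one entry per class")
        means = dict(zip(CLASS_ORDER, map(float, triple)))
    rho_min = min(means.values())
    rho_max = max(means.values())
    if rho_max <= 0:
        raise DomainError("class-average grades must be positive")
    if rho_min == rho_max:
        raise DegenerateHueError(
            "all class-average grades coincide; hue has no geometric meaning"
        )
    delta = rho_max - rho_min
    # inverted channels: the class with rho_max gets channel 0, rho_min gets 1
    r = (rho_max - means[DOSClass.III]) / delta
    g = (rho_max - means[DOSClass.I]) / delta
    b = (rho_max - means[DOSClass.II]) / delta

    winners = [c for c in CLASS_ORDER if means[c] == rho_max]
    low_confidence = len(winners) > 1
    branch_class = max(winners, key=_BRANCH_PRIORITY.__getitem__)

    diffs = {"g-b": g - b, "b-r": b - r, "r-g": r - g}
    selector, offset, wrap = _hue_branches(convention)[branch_class]
    H = 60.0 * diffs[selector] + offset
    if wrap:
        H = H % 360.0
    S = (rho_max - rho_min) / rho_max  # gamma == rho_max
    return HSVResult(r, g, b, H, S, rho_max, branch_class, low_confidence)


def hue_to_hc(H: float) -> float:
    """Hue fraction H_C = H / 360 in [0, 1]."""
    if not 0.0 <= H <= 360.0:
        raise DomainError(f"H must lie in [0, 360], got {H}")
    return H / 360.0


def circular_distance(x: float, y: float) -> float:
    """Distance on the unit circle [0, 1): min(|x - y|, 1 - |x - y|)."""
    d = abs(x - y) % 1.0
    return min(d, 1.0 - d)


def _predict_from_hc(hc: float, critical: Mapping[DOSClass, float]) -> DOSClass:
    return min(CLASS_ORDER, key=lambda c: circular_distance(hc, critical[c]))


def _rescale_grades(rho: np.ndarray) -> np.ndarray:
    lo, hi = float(rho.min()), float(rho.max())
    if hi == lo:
        return rho
    return (rho - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pattern(phi, model: CRAModel) -> ColorResult:
    """Classify one query pattern through the full CRA pipeline.

    A degenerate hue (all class means equal) yields an unclassifiable result
    rather than an exception, so batch runs can proceed.
    """
    if isinstance(phi, FeaturePattern):
        subject_id, true_class, vec = phi.subject_id, phi.dos_class, phi.phi
    else:
        subject_id, true_class, vec = None, None, np.asarray(phi, dtype=float)
    if vec.shape != (6,):
        raise DomainError(f"query pattern must be a 6-vector, got shape {vec.shape}")

    X = model.training.matrix
    ED = np.linalg.norm(X - vec, axis=1)
    rho = model.xi * np.exp(-model.xi * ED)
    graded = _rescale_grades(rho) if model.intensity_rescale else rho
    rho_ave, rho_min, rho_max = class_average_grades(graded, model.training.labels)

    base = dict(
        grades_rho=rho,
        rho_ave=rho_ave,
        rho_min=rho_min,
        rho_max=rho_max,
        subject_id=subject_id,
        true_class=true_class,
    )
    try:
        hsv = hsv_transform(rho_ave, model.hue_branch_convention)
    except DegenerateHueError:
        return ColorResult(unclassifiable=True, **base)
    hc = hue_to_hc(hsv.H)
    return ColorResult(
        rgb=(hsv.r, hsv.g, hsv.b),
        hue_H=hsv.H,
        saturation_S=hsv.S,
        value_gamma=hsv.gamma,
        H_C=hc,
        predicted_class=_predict_from_hc(hc, model.critical_HC),
        low_confidence=hsv.low_confidence,
        **base,
    )


def msef(predictions, targets, error_mode: str = "wrapped") -> float:
    """Mean squared error function between target decisions and realised H_C.

    ``targets`` may be DOSClass labels (mapped to the critical decisions
    2/3, 1/3, 1) or numeric decision values.  ``wrapped`` uses the circular
    difference on [0, 1); ``plain`` uses T - H_C literally.
    """
    preds = list(predictions)
    targs = list(targets)
    if not preds or len(preds) != len(targs):
        raise DomainError("predictions and targets must be nonempty, equal length")
    if error_mode not in ("wrapped", "plain"):
        raise DomainError(f"unknown error mode {error_mode!r}")
    total = 0.0
    for h, t in zip(preds, targs):
        tv = CRITICAL_HC[DOSClass(t)] if isinstance(t, (DOSClass, str)) else float(t)
        if h is None:  # unclassifiable pattern: charge the maximum wrapped error
            total += MAX_WRAPPED_SQERR
            continue
        err = circular_distance(float(h), tv) if error_mode == "wrapped" else tv - float(h)
        total += err * err
    return total / len(preds)


# ---------------------------------------------------------------------------
# leave-one-out fitness (used by the swarm optimizer)
# ---------------------------------------------------------------------------

def loo_msef_function(
    training: TrainingSet,
    convention: str = "class_centered",
    error_mode: str = "wrapped",
    intensity_rescale: bool = False,
) -> Callable[[float], float]:
    """Build xi -> leave-one-out MSEF over the training set.

    Each training pattern is classified against the other K-1 patterns
    (leaving it in would plant a self-match at ED = 0 whose grade xi
    dominates every class mean as xi grows, making the resubstitution
    optimum degenerate).  The pairwise distance matrix is precomputed, so
    each fitness call costs O(K^2) elementary operations.
    """
    X = training.matrix
    labels = training.labels
    K = len(training)
    D = cdist(X, X)
    critical = dict(CRITICAL_HC)
    targets = np.array([critical[lab] for lab in labels])
    masks = {c: np.array([lab is c for lab in labels]) for c in CLASS_ORDER}
    for c in CLASS_ORDER:
        if masks[c].sum() < 2:
            raise DomainError(
                f"leave-one-out fitness needs >= 2 patterns in Class {c.value}"
            )
    eye = np.eye(K, dtype=bool)

    def fitness(xi: float) -> float:
        if xi <= 0:
            raise DomainError(f"xi must be positive, got {xi}")
        R = xi * np.exp(-xi * D)
        total = 0.0
        for k in range(K):
            keep = ~eye[k]
            row = R[k]
            if intensity_rescale:
                row = _rescale_grades(row[keep])
                means = {}
                labs = [lab for j, lab in enumerate(labels) if j != k]
                for c in CLASS_ORDER:
                    sel = [v for v, lab in zip(row, labs) if lab is c]
                    means[c] = float(np.mean(sel))
            else:
                means = {}
                for c in CLASS_ORDER:
                    sel = masks[c] & keep
                    means[c] = float(row[sel].mean())
            try:
                hsv = hsv_transform(means, convention)
            except DegenerateHueError:
                total += MAX_WRAPPED_SQERR
                continue
            hc = hue_to_hc(hsv.H)
            if error_mode == "wrapped":
                err = circular_distance(hc, targets[k])
            else:
                err = targets[k] - hc
            total += err * err
        return total / K

    return fitness


def loo_msef(
    training: TrainingSet,
    xi: float,
    convention: str = "class_centered",
    error_mode: str = "wrapped",
    intensity_rescale: bool = False,
) -> float:
    """Leave-one-out MSEF of the CRA at a given recognition coefficient."""
    return loo_msef_function(training, convention, error_mode, intensity_rescale)(xi)


def evaluate(model: CRAModel, patterns: Iterable[FeaturePattern]) -> EvaluationResult:
    """Accuracy and 3x3 confusion table of a model on labelled patterns."""
    pats = list(patterns)
    if not pats:
        raise DomainError("nothing to evaluate")
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    confusion = np.zeros((3, 3), dtype=int)
    results = []
    correct = 0
    for p in pats:
        if p.dos_class is None:
            raise DomainError("evaluate requires labelled patterns")
        res = classify_pattern(p, model)
        results.append(res)
        if res.predicted_class is not None:
            confusion[idx[p.dos_class], idx[res.predicted_class]] += 1
            if res.predicted_class is p.dos_class:
                correct += 1
    return EvaluationResult(
        accuracy=correct / len(pats), confusion=confusion, results=tuple(results)
    )
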