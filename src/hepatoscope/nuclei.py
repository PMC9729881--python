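"""Nuclear-morphology cell classification with stepwise binuclear reclassification.

Hepatocyte nuclei are large, round and evenly spaced; non-parenchymal
(immune/endothelial/biliary) nuclei are smaller, more elongated and often
clustered.  A depth-limited decision tree separates the two on morphology
and intensity features.  Binucleated hepatocytes cannot be told apart from
dense touching non-hepatocyte nuclei by per-nucleus features alone, so they
are recovered afterwards by an ordered rule cascade over touching pairs of
hepatocyte-predicted nuclei.  Model quality is reported as a binary error
matrix with nine derived statistics (PPV, NPV, sensitivity, specificity,
accuracy, falsePos/realPos, FDR, FNR, FOR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASS_HEPATOCYTE",
    "CLASS_BINUCLEAR",
    "CLASS_OTHER",
    "TYPICAL_NUCLEUS_AREA_UM2",
    "FEATURE_NAMES",
    "NucleusRecord",
    "TreeConfig",
    "TreeModel",
    "BinuclearRules",
    "ErrorMatrix",
    "binary_label",
    "stratified_split",
    "train_tree",
    "iterative_tune",
    "reclassify_binuclear",
    "error_matrix",
    "reconstruct_confusion",
    "class_density",
]

CLASS_HEPATOCYTE = "Hepatocyte"
CLASS_BINUCLEAR = "Binuclear"
CLASS_OTHER = "nonHepatocyte"
_CLASSES = (CLASS_HEPATOCYTE, CLASS_BINUCLEAR, CLASS_OTHER)

#: typical cross-sectional area of a hepatocyte nucleus, µm²
TYPICAL_NUCLEUS_AREA_UM2 = 70.0

FEATURE_NAMES = (
    "area",
    "perimeter",
    "circularity",
    "elongation",
    "intensity_mean",
    "intensity_sd",
    "nn_distance",
    "touching_count",
)


@dataclass
class NucleusRecord:
    """One detected nucleus: centroid, morphology/intensity/context features,
    ground-truth class and (after classification) predicted class."""

    id: int
    x: float
    y: float
    area: float
    perimeter: float
    circularity: float
    elongation: float
    intensity_mean: float
    intensity_sd: float
    nn_distance: float
    touching_count: int
    true_class: str
    predicted_class: str | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if not (0 < self.circularity <= 1):
            raise ValueError("circularity must be in (0, 1]")
        if self.elongation < 1:
            raise ValueError("elongation (major/minor) must be >= 1")
        if self.true_class not in _CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")

    def features(self) -> list[float]:
        return [getattr(self, f) for f in FEATURE_NAMES]


def binary_label(cls: str) -> str:
    """Collapse the taxonomy to the binary task the tree is trained on.

    Binucleated hepatocytes are hepatocytes; the tree only separates
    hepatocyte-like from non-hepatocyte nuclei.
    """
    return CLASS_HEPATOCYTE if cls in (CLASS_HEPATOCYTE, CLASS_BINUCLEAR) else CLASS_OTHER


@dataclass(frozen=True)
class TreeConfig:
    """Decision-tree training configuration (depth-limited CART)."""

    max_depth: int = 7
    min_samples_per_leaf: int = 1
    cv_folds: int = 5
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.min_samples_per_leaf < 1:
            raise ValueError("min_samples_per_leaf must be >= 1")


def stratified_split(
    records: Sequence[NucleusRecord], config: TreeConfig
) -> tuple[list[NucleusRecord], list[NucleusRecord]]:
    """Per-class train/test partition at ``train_fraction``.

    The train size per class is the nearest integer to fraction·n; the
    remainder goes to test.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    by_class: dict[str, list[NucleusRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.true_class, []).append(rec)
    train: list[NucleusRecord] = []
    test: list[NucleusRecord] = []
    for cls, recs in by_class.items():
        if len(recs) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 records; cannot split")
        order = rng.permutation(len(recs))
        n_train = round(config.train_fraction * len(recs))
        n_train = min(max(n_train, 1), len(recs) - 1)  # keep both sides non-empty
        for i in order[:n_train]:
            train.append(recs[i])
        for i in order[n_train:]:
            test.append(recs[i])
    return train, test


@dataclass
class TreeModel:
    """A fitted hepatocyte-vs-rest decision tree plus its CV score."""

    estimator: DecisionTreeClassifier
    config: TreeConfig
    cv_scores: np.ndarray

    @property
    def cv_mean(self) -> float:
        return float(self.cv_scores.mean())

    def predict(self, records: Iterable[NucleusRecord]) -> list[NucleusRecord]:
        """Return records with ``predicted_class`` set (binary labels)."""
        recs = list(records)
        X = np.array([r.features() for r in recs])
        pred = self.estimator.predict(X)
        return [replace(r, predicted_class=p) for r, p in zip(recs, pred)]


def train_tree(
    train: Sequence[NucleusRecord], config: TreeConfig = TreeConfig()
) -> TreeModel:
    """Fit the binary depth-limited CART tree on morphology features.

    Binuclear ground truth collapses to Hepatocyte for this stage.  The
    cross-validated accuracy (``cv_folds`` stratified folds) is recorded for
    tuning; the returned estimator is refitted on all of ``train``.
    """
    X = np.array([r.features() for r in train])
    y = np.array([binary_label(r.true_class) for r in train])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both binary classes")
    est = DecisionTreeClassifier(
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_per_leaf,
        random_state=config.seed,
    )
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    scores = cross_val_score(est, X, y, cv=cv)
    est.fit(X, y)
    return TreeModel(estimator=est, config=config, cv_scores=scores)


# ---------------------------------------------------------------------------
# error matrix


@dataclass
class ErrorMatrix:
    """Binary confusion counts and the nine derived proportions.

    Ratios are computed in exact rational arithmetic and exposed as floats;
    a zero denominator yields ``nan`` and the statistic's name in ``flags``.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str = CLASS_HEPATOCYTE
    flags: list[str] = field(default_factory=list)

    STAT_NAMES = (
        "PPV",
        "NPV",
        "sensitivity",
        "specificity",
        "accuracy",
        "falsePos_over_realPos",
        "FDR",
        "FNR",
        "FOR",
    )

    def _ratio(self, num: int, den: int, name: str) -> float:
        if den == 0:
            if name not in self.flags:
                self.flags.append(name)
            return math.nan
        return float(Fraction(num, den))

    @property
    def PPV(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp, "PPV")

    @property
    def NPV(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn, "NPV")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn, "sensitivity")

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp, "specificity")

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.fn + self.tn, "accuracy")

    @property
    def falsePos_over_realPos(self) -> float:
        return self._ratio(self.fp, self.tp + self.fn, "falsePos_over_realPos")

    @property
    def FDR(self) -> float:
        return self._ratio(self.fp, self.tp + self.fp, "FDR")

    @property
    def FNR(self) -> float:
        return self._ratio(self.fn, self.tp + self.fn, "FNR")

    @property
    def FOR(self) -> float:
        return self._ratio(self.fn, self.tn + self.fn, "FOR")

    def statistics(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.STAT_NAMES}

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        """Statistics rounded for display (4 decimals by convention)."""
        return {k: round(v, ndigits) for k, v in self.statistics().items()}


def error_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive_class: str = CLASS_HEPATOCYTE,
) -> ErrorMatrix:
    """Binary confusion matrix of ``positive_class`` versus everything else."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if len(t) != len(p):
        raise ValueError(f"label length mismatch: {len(t)} true vs {len(p)} predicted")
    tpos = t == positive_class
    ppos = p == positive_class
    return ErrorMatrix(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        positive_class=positive_class,
    )


def reconstruct_confusion(
    n_positives: int, n_negatives: int, sensitivity: float, specificity: float
) -> tuple[int, int, int, int]:
    """Integer confusion counts (TP, FN, TN, FP) from set sizes and rates.

    TP = round(n_pos·sens), FN = n_pos − TP, TN = round(n_neg·spec),
    FP = n_neg − TN.  Lets a published error-matrix row (given only
    population sizes and per-class rates) be rebuilt exactly.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must be in [0, 1]")
    if n_positives < 0 or n_negatives < 0:
        raise ValueError("counts must be >= 0")
    tp = round(n_positives * sensitivity)
    tn = round(n_negatives * specificity)
    return tp, n_positives - tp, tn, n_negatives - tn


# ---------------------------------------------------------------------------
# tuning


def iterative_tune(
    train: Sequence[NucleusRecord],
    test: Sequence[NucleusRecord],
    grid: Sequence[TreeConfig],
) -> tuple[TreeConfig, dict]:
    """Choose the tree config whose train/test error-matrix statistics are
    most nearly equal (min over the grid of the max absolute train−test gap
    across the nine statistics).  Ties break toward smaller depth.

    Returns the chosen config and a per-config report of gaps and matrices.
    """
    if not grid:
        raise ValueError("empty tuning grid")
    y_train = [binary_label(r.true_class) for r in train]
    y_test = [binary_label(r.true_class) for r in test]
    report = {}
    scored = []
    for cfg in grid:
        model = train_tree(train, cfg)
        em_train = error_matrix(
            y_train, [r.predicted_class for r in model.predict(train)]
        )
        em_test = error_matrix(
            y_test, [r.predicted_class for r in model.predict(test)]
        )
        s_tr, s_te = em_train.statistics(), em_test.statistics()
        gaps = [
            abs(s_tr[k] - s_te[k])
            for k in ErrorMatrix.STAT_NAMES
            if not (math.isnan(s_tr[k]) or math.isnan(s_te[k]))
        ]
        balance = max(gaps) if gaps else math.inf
        report[cfg] = {"balance": balance, "train": s_tr, "test": s_te}
        scored.append((balance, cfg.max_depth, cfg))
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][2], report


# ---------------------------------------------------------------------------
# binuclear reclassification cascade


@dataclass(frozen=True)
class BinuclearRules:
    """Thresholds of the stepwise binuclear reassignment.

    A binucleated hepatocyte presents as two touching hepatocyte-like
    nuclei whose combined area is that of roughly one-and-a-half to
    two-and-a-half typical nuclei; nuclei embedded in dense mutually
    touching clusters are non-hepatocyte context and excluded.
    """

    touching_distance: float = 12.0
    combined_area_min: float = 1.4  # × typical nucleus area
    combined_area_max: float = 2.6
    typical_area: float = TYPICAL_NUCLEUS_AREA_UM2
    clique_size: int = 3  # exclusion threshold for mutually touching cliques


def reclassify_binuclear(
    records: Sequence[NucleusRecord], rules: BinuclearRules = BinuclearRules()
) -> tuple[list[NucleusRecord], list[dict]]:
    """Ordered rule cascade promoting touching hepatocyte pairs to Binuclear.

    R1: candidate pairs are two Hepatocyte-predicted nuclei with centroid
        separation ≤ touching_distance.
    R2: the pair's combined area must fall within
        [combined_area_min, combined_area_max] × typical_area.
    R3: a nucleus participating in a clique of ≥ clique_size mutually
        touching nuclei (dense cluster context) is never reassigned.
    Surviving pairs have both members set to Binuclear.  Returns the updated
    records and an audit log (rule name, pairs in/out).  Applying the
    cascade twice is a no-op on the second pass: promoted nuclei are no
    longer Hepatocyte-predicted.
    """
    recs = [replace(r) for r in records]
    audit: list[dict] = []
    if not recs:
        return recs, audit
    xy = np.array([[r.x, r.y] for r in recs])
    tree = cKDTree(xy)
    all_pairs = tree.query_pairs(rules.touching_distance)

    # adjacency over all nuclei, for clique context
    adj: dict[int, set[int]] = {i: set() for i in range(len(recs))}
    for i, j in all_pairs:
        adj[i].add(j)
        adj[j].add(i)
    in_clique = set()
    for i, j in all_pairs:
        if adj[i] & adj[j]:  # common touching neighbour => triangle
            in_clique.update((i, j))

    r1 = [
        (i, j)
        for i, j in all_pairs
        if recs[i].predicted_class == CLASS_HEPATOCYTE
        and recs[j].predicted_class == CLASS_HEPATOCYTE
    ]
    audit.append({"rule": "R1_touching_hepatocyte_pairs", "pairs": len(r1)})

    lo = rules.combined_area_min * rules.typical_area
    hi = rules.combined_area_max * rules.typical_area
    r2 = [(i, j) for i, j in r1 if lo <= recs[i].area + recs[j].area <= hi]
    audit.append({"rule": "R2_combined_area_window", "pairs": len(r2)})

    r3 = [(i, j) for i, j in r2 if i not in in_clique and j not in in_clique]
    audit.append({"rule": "R3_clique_exclusion", "pairs": len(r3)})

    reassigned = set()
    for i, j in r3:
        reassigned.update((i, j))
    for i in reassigned:
        recs[i] = replace(recs[i], predicted_class=CLASS_BINUCLEAR)
    audit.append({"rule": "reassigned_to_binuclear", "nuclei": len(reassigned)})
    return recs, audit


def class_density(
    records: Sequence[NucleusRecord], tissue_area_mm2: float, use: str = "auto"
) -> dict[str, float]:
    """Nuclei per mm² for each class in the taxonomy.

    ``use`` selects the label source: "predicted", "true", or "auto"
    (predicted when populated on every record, else ground truth).
    """
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be > 0")
    if use == "auto":
        use = (
            "predicted"
            if records and all(r.predicted_class is not None for r in records)
            else "true"
        )
    attr = {"predicted": "predicted_class", "true": "true_class"}[use]
    out = {cls: 0.0 for cls in _CLASSES}
    for r in records:
        label = getattr(r, attr)
        out[label] = out.get(label, 0.0) + 1.0
    return {cls: n / tissue_area_mm2 for cls, n in out.items()}
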