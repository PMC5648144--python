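"""Accuracy metrics, patch shape index, and whole-map rank correlation.

Threshold-dependent skill (TPR, TSS) is computed on the spatially held-out
fold at the threshold chosen on the training fold; AUC is the rank-based
(Mann-Whitney) threshold-independent complement.  The spatial complexity of
a binarized prediction is summarized by the landscape shape index
``SI = Σ 0.25 p_i / sqrt(a_i)`` over connected patches of suitable cells
(area ``a_i`` in cells, perimeter ``p_i`` in cell edges): every square patch
contributes exactly 1, irregular patches more.  Whole-map similarity
between two suitability surfaces uses Kendall's tau-b over jointly valid
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .raster import GridLayer, GridStack
from .design import TrainingPoints
from .models import predict_raster, select_threshold

__all__ = [
    "confusion_metrics",
    "auc",
    "label_patches",
    "shape_index",
    "kendall_map_tau",
    "binarize",
    "evaluate_treatment",
    "EvalRecord",
    "PatchSet",
]


@dataclass
class EvalRecord:
    """One row of the factorial results table."""

    species_id: str
    predictor_label: str
    algorithm: str
    TSS: float
    TPR: float
    AUC: float
    SI: float
    threshold: float
    n_train: int
    n_test: int
    chosen_resolution: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = d.pop("species_id")
        d["predictor"] = d.pop("predictor_label")
        d["resolution"] = d.pop("chosen_resolution")
        return d


@dataclass
class PatchSet:
    patches: list[tuple[int, int]]  # (area in cells, perimeter in edges)


def confusion_metrics(obs, pred_binary) -> tuple[float, float, float]:
    """(TPR, TNR, TSS) from binary observations and predictions."""
    obs = np.asarray(obs).astype(int)
    pred = np.asarray(pred_binary).astype(int)
    if np.unique(obs).size < 2:
        raise ValueError("confusion metrics need both classes observed")
    tp = int(((obs == 1) & (pred == 1)).sum())
    fn = int(((obs == 1) & (pred == 0)).sum())
    tn = int(((obs == 0) & (pred == 0)).sum())
    fp = int(((obs == 0) & (pred == 1)).sum())
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    return tpr, tnr, tpr + tnr - 1.0


def auc(obs, scores) -> float:
    """Rank-based AUC (ties count one half)."""
    obs = np.asarray(obs).astype(int)
    if np.unique(obs).size < 2:
        raise ValueError("AUC needs both classes observed")
    return float(roc_auc_score(obs, np.asarray(scores, float)))


def label_patches(binary: GridLayer | np.ndarray, connectivity: int = 4) -> PatchSet:
    """Connected patches of suitable cells with areas and edge perimeters.

    ``binary`` marks suitable cells truthy; invalid cells count as
    non-suitable.  Perimeter counts cell edges adjacent to non-suitable,
    invalid, or off-grid territory (edge counting is the same for 4- and
    8-connectivity; connectivity only changes which cells merge into one
    patch).
    """
    if isinstance(binary, GridLayer):
        grid = (binary.values > 0) & binary.valid
    else:
        grid = np.asarray(binary) > 0
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(grid, structure=structure)
    if n == 0:
        return PatchSet([])
    areas = ndimage.sum_labels(grid, labels, index=np.arange(1, n + 1)).astype(int)
    # interior shared edges per label: horizontal + vertical same-label pairs
    horiz = (labels[:, :-1] == labels[:, 1:]) & (labels[:, :-1] > 0)
    vert = (labels[:-1, :] == labels[1:, :]) & (labels[:-1, :] > 0)
    shared = np.zeros(n + 1, dtype=int)
    np.add.at(shared, labels[:, :-1][horiz], 1)
    np.add.at(shared, labels[:-1, :][vert], 1)
    perims = 4 * areas - 2 * shared[1:]
    return PatchSet(list(zip(areas.tolist(), perims.tolist())))


def shape_index(patches: PatchSet) -> float:
    """SI = Σ 0.25 p_i / sqrt(a_i); 0 for an empty map."""
    return float(sum(0.25 * p / np.sqrt(a) for a, p in patches.patches))


def binarize(layer: GridLayer, threshold: float) -> GridLayer:
    """Suitability >= threshold -> 1 over valid cells."""
    vals = np.where(layer.valid, (layer.values >= threshold).astype(float), np.nan)
    return layer.copy(values=vals, name=f"{layer.name}_binary")


def kendall_map_tau(layer_a: GridLayer, layer_b: GridLayer) -> float:
    """Kendall tau-b between two co-registered suitability maps."""
    if not layer_a.same_geometry(layer_b):
        raise ValueError("layers are not co-registered")
    joint = layer_a.valid & layer_b.valid
    a = layer_a.values[joint]
    b = layer_b.values[joint]
    if a.size < 2:
        raise ValueError("fewer than 2 jointly valid cells")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance layer in tau comparison")
    res = sps.kendalltau(a, b, variant="b")
    return float(res.statistic)


def evaluate_treatment(
    points: TrainingPoints,
    scores: GridStack,
    make_model,
    predictor_label: str,
    algorithm: str,
    background: np.ndarray | None = None,
    connectivity: int = 4,
) -> tuple[EvalRecord, GridLayer]:
    """Two-fold spatially blocked evaluation of one treatment.

    For each fold the model is fitted on the training bin (for a
    presence/background learner, ``background`` rows replace the
    pseudo-absences at fit time), the threshold maximizing sensitivity +
    specificity is chosen on training points, and TPR/TSS (at that
    threshold) plus AUC are computed on the held-out bin.  SI is measured on
    the binarized full-extent prediction of each fold; all metrics are
    averaged over the two folds.  Returns the record and the mean of the two
    fold suitability maps (used for whole-map comparisons).
    """
    X, ok = points.extract(scores)
    if not ok.all():
        # points on invalid cells cannot be scored; they were flagged upstream
        raise ValueError("training points fall on invalid predictor cells")
    y = points.y
    bins = points.bin
    metrics = []
    maps = []
    for train_bin, test_bin in ((1, 2), (2, 1)):
        tr = bins == train_bin
        te = bins == test_bin
        model = make_model()
        if background is not None:
            fit_X = np.vstack([X[tr & (y == 1)], background])
            fit_y = np.concatenate(
                [np.ones((tr & (y == 1)).sum(), int), np.zeros(len(background), int)]
            )
        else:
            fit_X, fit_y = X[tr], y[tr]
        model.fit(fit_X, fit_y)
        pred_tr = model.predict_proba(X[tr])[:, 1]
        thr = select_threshold(y[tr], pred_tr)
        pred_te = model.predict_proba(X[te])[:, 1]
        tpr, _, tss = confusion_metrics(y[te], (pred_te >= thr).astype(int))
        fold_auc = auc(y[te], pred_te)
        smap = predict_raster(model, scores)
        si = shape_index(label_patches(binarize(smap, thr), connectivity))
        metrics.append((tss, tpr, fold_auc, si, thr, int(tr.sum()), int(te.sum())))
        maps.append(smap)
    arr = np.array([m[:5] for m in metrics], float)
    joint = maps[0].valid & maps[1].valid
    mean_vals = np.where(joint, (maps[0].values + maps[1].values) / 2.0, np.nan)
    mean_map = maps[0].copy(values=mean_vals, valid=joint)
    rec = EvalRecord(
        species_id=points.species_id,
        predictor_label=predictor_label,
        algorithm=algorithm,
        TSS=float(arr[:, 0].mean()),
        TPR=float(arr[:, 1].mean()),
        AUC=float(arr[:, 2].mean()),
        SI=float(arr[:, 3].mean()),
        threshold=float(arr[:, 4].mean()),
        n_train=metrics[0][5],
        n_test=metrics[0][6],
        chosen_resolution=points.chosen_resolution,
    )
    return rec, mean_map
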