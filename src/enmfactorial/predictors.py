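"""Predictor-set construction: PCA score stacks retaining >95% variance.

Raw climate and soil layers are strongly collinear, and the modeled
algorithms differ in how badly collinearity hurts them.  Instead of feeding
raw variables to the models, each variable family is standardized (mean 0,
SD 1 over jointly valid cells) and eigendecomposed via its correlation
matrix; the minimal number of leading components whose cumulative explained
variance *exceeds* the threshold (default 0.95) is retained and their score
surfaces become the model predictors.  Three sets are built: climate-only
(C), edaphic-only (E) and the concatenation (CE), each with its own PCA.

Component signs are arbitrary; for reproducibility each component is
flipped so that its largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridLayer, GridStack

__all__ = ["PredictorSet", "fit_pca_predictors", "build_sets"]


@dataclass
class PredictorSet:
    """A fitted PCA over one variable family plus its score layers."""

    label: str
    score_layers: GridStack
    loadings: np.ndarray        # variables x retained components (orthonormal cols)
    eigenvalues: np.ndarray     # all components, descending
    cum_var: np.ndarray         # cumulative proportion, all components
    k: int
    means: np.ndarray           # per-variable standardization constants
    sds: np.ndarray
    variable_names: list[str]

    @property
    def pc1(self) -> GridLayer:
        return self.score_layers.layers[0]

    def project(self, stack: GridStack) -> GridStack:
        """Apply the stored standardization + loadings to a co-registered stack."""
        try:
            sub = stack.subset(self.variable_names)
        except KeyError as exc:
            raise ValueError(f"stack lacks fitted variable {exc.args[0]!r}") from exc
        mat, _ = sub.to_matrix(where_valid=False)
        Z = (mat - self.means) / self.sds
        scores = Z @ self.loadings
        geom = stack.geometry
        nr, nc = geom.shape
        jv = sub.joint_valid
        layers = []
        for c in range(self.k):
            vals = scores[:, c].reshape(nr, nc)
            vals = np.where(jv, vals, np.nan)
            layers.append(
                GridLayer(
                    name=f"{self.label}_pc{c + 1}",
                    values=vals,
                    valid=jv,
                    origin_x=geom.origin_x,
                    origin_y=geom.origin_y,
                    cell_size=geom.cell_size,
                    crs_label=geom.crs_label,
                )
            )
        return GridStack(layers)


def fit_pca_predictors(
    stack: GridStack, threshold: float = 0.95, label: str = "PC"
) -> PredictorSet:
    """Correlation-matrix PCA over the jointly valid cells of ``stack``.

    Retains the minimal k with cumulative explained variance strictly above
    ``threshold``.  Constant layers and thresholds outside (0, 1] are
    rejected.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(stack) < 2:
        raise ValueError("PCA needs at least two layers")
    mat, _ = stack.to_matrix(where_valid=True)
    if mat.shape[0] <= len(stack):
        raise ValueError("not enough jointly valid cells for PCA")
    means = mat.mean(axis=0)
    sds = mat.std(axis=0)
    if np.any(sds == 0):
        bad = [n for n, s in zip(stack.names, sds) if s == 0]
        raise ValueError(f"constant layer(s): {bad}")
    Z = (mat - means) / sds
    corr = (Z.T @ Z) / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # pin signs: largest |loading| per component made positive
    for c in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[pivot, c] < 0:
            eigvec[:, c] *= -1
    cum = np.cumsum(eigval) / eigval.sum()
    k = int(np.searchsorted(cum, threshold, side="right") + 1)
    k = min(k, len(eigval))

    ps = PredictorSet(
        label=label,
        score_layers=None,  # filled below via project()
        loadings=eigvec[:, :k],
        eigenvalues=eigval,
        cum_var=cum,
        k=k,
        means=means,
        sds=sds,
        variable_names=list(stack.names),
    )
    ps.score_layers = ps.project(stack)
    return ps


def build_sets(
    climate: GridStack, edaphic: GridStack, threshold: float = 0.95
) -> dict[str, PredictorSet]:
    """Fit the three independent PCAs: C (climate), E (edaphic), CE (both)."""
    if not climate.geometry.same_geometry(edaphic.geometry):
        raise ValueError("climate and edaphic stacks are not co-registered")
    combined = climate.concat(edaphic)
    return {
        "C": fit_pca_predictors(climate, threshold, label="C"),
        "E": fit_pca_predictors(edaphic, threshold, label="E"),
        "CE": fit_pca_predictors(combined, threshold, label="CE"),
    }
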