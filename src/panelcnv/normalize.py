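"""The RDr -> RDrp -> X normalization chain.

Three staged transforms turn raw per-bin depth into a copy-ratio-like
quantity X that is comparable across specimens and target groups:

(a) RDr   — each group's depth divided by the specimen's mean depth over
            unmasked single-bin groups (removes library size);
(b) RDrp  — RDr after removal of the top principal components of the
            training cohort's specimen-centered RDr (removes systematic
            capture/batch structure while leaving sparse CNV signal);
(c) X     — RDrp divided by the specimen's median RDrp over single-bin
            groups (re-anchors the diploid baseline at 1).

The per-specimen denominators are always computed over unmasked
single-bin groups and reused for every group level, keeping levels on a
common scale.  All ratios are on the natural scale (no log transform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .coverage import DepthMatrix
from .panel import Panel

__all__ = [
    "NormalizedMatrix",
    "PcaBasis",
    "group_depth",
    "compute_rdr",
    "fit_pca",
    "apply_pca",
    "median_normalize",
    "normalize_to_x",
    "choose_n_components",
]


@dataclass
class NormalizedMatrix:
    """A staged matrix (groups x specimens) plus per-group stratum labels."""

    stage: str  # RDr | RDrp | X
    values: pd.DataFrame
    strata: pd.Series  # group_id -> stratum (single_bin, exon, window2, ...)
    unscorable_specimens: tuple[str, ...] = ()

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_ids(self) -> list[str]:
        return list(self.values.index)

    def single_bin_mask(self) -> np.ndarray:
        return (self.strata == "single_bin").to_numpy()


@dataclass
class PcaBasis:
    """Per-group training means + top-k loading vectors over groups.

    ``scale`` is the per-group robust spread (scaled MAD) of training RDr;
    projection scores are estimated on data winsorized at ``clip_mads``
    robust deviations so that sparse CNV signal (a deleted gene sits ~10
    MADs out) cannot leak into the removed component and smear across the
    panel.  Systematic technical structure, which is what PCA is meant to
    remove, lives well inside the clip bounds.
    """

    group_ids: tuple[str, ...]
    mean: np.ndarray  # (G,)
    components: np.ndarray  # (k, G), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,)
    scale: np.ndarray | None = None  # (G,)
    clip_mads: float = 3.0

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def group_depth(matrix: DepthMatrix, panel: Panel) -> DepthMatrix:
    """Aggregate bin depth to target groups (length-weighted mean).

    The weighted mean over member bins equals the per-base mean depth over
    the whole group, keeping bin- and group-level statistics consistent.
    """
    if not panel.groups:
        raise ValueError("panel has no target groups; run make_target_groups first")
    bin_index = {tid: i for i, tid in enumerate(matrix.values.index)}
    lengths = {t.target_id: t.length for t in panel.targets if t.kind == "bin"}
    rows, cols, weights = [], [], []
    group_ids = []
    for gi, g in enumerate(panel.groups):
        total = sum(lengths[m] for m in g.member_target_ids)
        group_ids.append(g.group_id)
        for m in g.member_target_ids:
            if m not in bin_index:
                raise ValueError(f"group {g.group_id}: bin {m} missing from depth matrix")
            rows.append(gi)
            cols.append(bin_index[m])
            weights.append(lengths[m] / total)
    w = sparse.csr_matrix(
        (weights, (rows, cols)), shape=(len(panel.groups), len(matrix.values.index))
    )
    values = pd.DataFrame(
        w @ matrix.values.to_numpy(), index=group_ids, columns=matrix.values.columns
    )
    return DepthMatrix(
        values=values,
        batch_labels=matrix.batch_labels.copy(),
        specimen_qc_pass=matrix.specimen_qc_pass.copy(),
        target_qc_pass=pd.Series(True, index=group_ids),
    )


def _strata_series(panel: Panel) -> pd.Series:
    return pd.Series({g.group_id: g.stratum for g in panel.groups})


def compute_rdr(matrix: DepthMatrix, panel: Panel) -> NormalizedMatrix:
    """Relative read depth: divide by the specimen mean over single bins."""
    strata = _strata_series(panel).reindex(matrix.values.index)
    if strata.isna().any():
        missing = strata.index[strata.isna()][0]
        raise ValueError(f"group {missing!r} not present in panel")
    sb = (strata == "single_bin").to_numpy()
    denom = matrix.values.to_numpy()[sb].mean(axis=0)
    unscorable = tuple(matrix.values.columns[denom <= 0])
    safe = np.where(denom > 0, denom, np.nan)
    values = matrix.values / safe
    return NormalizedMatrix("RDr", values, strata, unscorable)


def choose_n_components(
    explained_variance_ratio: np.ndarray, n_components: int = 5, var_target: float = 0.90
) -> int:
    """Cap k at the number of components explaining ``var_target`` variance."""
    cum = np.cumsum(explained_variance_ratio)
    reach = np.searchsorted(cum, var_target) + 1
    if cum.size and cum[-1] < var_target:
        reach = len(cum)
    return int(min(n_components, reach))


def fit_pca(
    training: NormalizedMatrix,
    n_components: int = 5,
    var_target: float | None = 0.90,
) -> PcaBasis:
    """Fit the denoising basis on training RDr.

    Specimens are observations, groups are variables; the basis holds the
    per-group training mean and the top-k orthonormal loading vectors of
    the specimen-centered RDr.  ``var_target`` caps k at the component
    count already explaining that share of training variance.
    """
    from sklearn.decomposition import PCA

    data = training.values.to_numpy().T  # specimens x groups
    n_s, n_g = data.shape
    if n_components > 0 and n_s < n_components + 2:
        raise ValueError(
            f"need >= n_components + 2 training specimens (got {n_s} for k={n_components})"
        )
    if n_components >= min(n_s, n_g) and n_components > 0:
        raise ValueError(f"n_components={n_components} >= min matrix dimension")
    mean = data.mean(axis=0)
    med = np.median(data, axis=0)
    scale = 1.4826 * np.median(np.abs(data - med), axis=0)
    if n_components == 0:
        return PcaBasis(
            group_ids=tuple(training.group_ids),
            mean=mean,
            components=np.empty((0, n_g)),
            explained_variance_ratio=np.empty(0),
            scale=scale,
        )
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    pca.fit(data)
    k = (
        choose_n_components(pca.explained_variance_ratio_, n_components, var_target)
        if var_target is not None
        else n_components
    )
    return PcaBasis(
        group_ids=tuple(training.group_ids),
        mean=mean,
        components=pca.components_[:k],
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
        scale=scale,
    )


def apply_pca(matrix: NormalizedMatrix, basis: PcaBasis) -> NormalizedMatrix:
    """Remove the basis-spanned component of (RDr - mean); keep the residual.

    RDrp(s,.) = mean + [(RDr(s,.) - mean) - proj_basis(RDr(s,.) - mean)].
    Projection scores are estimated on the winsorized centered vector
    (see :class:`PcaBasis`), then the fitted technical component is
    subtracted from the *unclipped* data, so CNV signal passes through
    intact.  With an empty basis this is the identity.
    """
    if tuple(matrix.group_ids) != tuple(basis.group_ids):
        raise ValueError("basis group ids do not match matrix group ids")
    data = matrix.values.to_numpy().T  # specimens x groups
    centered = data - basis.mean
    if basis.n_components > 0:
        v = basis.components  # (k, G)
        if basis.scale is not None:
            lim = basis.clip_mads * basis.scale
            scores = np.clip(centered, -lim, lim) @ v.T
        else:
            scores = centered @ v.T
        centered = centered - scores @ v
    out = pd.DataFrame(
        (centered + basis.mean).T, index=matrix.values.index, columns=matrix.values.columns
    )
    return NormalizedMatrix("RDrp", out, matrix.strata, matrix.unscorable_specimens)


def median_normalize(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """X: divide by the specimen median RDrp over single-bin groups."""
    sb = matrix.single_bin_mask()
    denom = np.median(matrix.values.to_numpy()[sb], axis=0)
    bad = denom <= 0
    unscorable = tuple(
        sorted(set(matrix.unscorable_specimens) | set(matrix.values.columns[bad]))
    )
    safe = np.where(denom > 0, denom, np.nan)
    values = matrix.values / safe
    return NormalizedMatrix("X", values, matrix.strata, unscorable)


def normalize_to_x(
    matrix: DepthMatrix, panel: Panel, basis: PcaBasis | None = None
) -> NormalizedMatrix:
    """Full chain bin depth -> group depth -> RDr -> RDrp -> X.

    With ``basis=None`` the PCA step is skipped (identity), which is the
    k=0 configuration.
    """
    gd = group_depth(matrix, panel)
    rdr = compute_rdr(gd, panel)
    rdrp = apply_pca(rdr, basis) if basis is not None else NormalizedMatrix(
        "RDrp", rdr.values, rdr.strata, rdr.unscorable_specimens
    )
    return median_normalize(rdrp)
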