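"""Sample- and fragment-level summaries: PCA, z-score heatmaps, volcano
tables, per-family abundance trends.

All tested artifacts are exported matrices and tables; figure rendering
is a thin optional layer on matplotlib/seaborn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .diffexpr import DesignInfo, significant

logger = logging.getLogger(__name__)


def variance_stabilize(cm: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1) — a simple monotone stabilizer.

    Doubling a sample's counts together with its size factor leaves its
    column unchanged, so the transform is normalization-equivariant.
    """
    if (np.asarray(sf, dtype=float) <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(cm / sf + 1.0)


@dataclass
class PCAProjection:
    coordinates: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x PCs

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w") as fh:
            evr = ",".join(f"{v:.6g}" for v in self.explained_variance_ratio)
            fh.write(f"# explained_variance_ratio: {evr}\n")
            self.coordinates.to_csv(fh, sep="\t", index_label="sample")
        return path


def run_pca(vst: pd.DataFrame, n_components: int | None = None) -> PCAProjection:
    """PCA of samples on centered variance-stabilized features.

    ``vst`` is features x samples (pipeline orientation).  The sign of
    each component is fixed so its largest-magnitude loading is
    positive, making projections deterministic across runs.
    """
    X = vst.to_numpy(dtype=float).T  # samples x features
    n_samples, n_features = X.shape
    if n_samples < 3 or n_features < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 features")
    k = n_components or min(n_samples, n_features)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    load = pca.components_.T  # features x k
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            coords[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCAProjection(
        coordinates=pd.DataFrame(coords, index=vst.columns, columns=pcs),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(load, index=vst.index, columns=pcs),
    )


def top_n_fragments(frag_table: pd.DataFrame, family_id: str, n: int = 20) -> list[str]:
    """Top-n fragment names of a family by total weighted count.

    Ties break by lexicographic name.  An absent family yields an empty
    list with a warning in the log.
    """
    from .fragannot import sample_columns

    fam = frag_table[frag_table["family_id"] == family_id]
    if fam.empty:
        logger.warning("family %s absent from fragment table", family_id)
        return []
    totals = fam[sample_columns(frag_table)].sum(axis=1)
    order = sorted(zip(-totals, fam["name"]))
    return [name for _neg, name in order[:n]]


@dataclass
class ZHeatmap:
    matrix: pd.DataFrame  # fragments x samples, row-wise z-scores
    row_order: list[str]
    linkage_description: str = "average linkage, Euclidean distance"

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.matrix.to_csv(path, sep="\t", index_label="fragment")
        order_path = path.with_suffix(".row_order.txt")
        order_path.write_text("\n".join(self.row_order) + "\n")
        return path


def zscore_heatmap(matrix: pd.DataFrame, fragments: list[str] | None = None) -> ZHeatmap:
    """Row-wise z-scores ordered by average-linkage clustering.

    Columns keep design order.  Constant rows become all-zero and are
    placed after the clustered rows.
    """
    if matrix.shape[1] < 2:
        raise ValueError("heatmap needs >= 2 samples")
    sub = matrix.loc[fragments] if fragments is not None else matrix
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    mean = X.mean(axis=1, keepdims=True)
    Z = np.zeros_like(X)
    nc = sd > 0
    Z[nc] = (X[nc] - mean[nc]) / sd[nc, None]
    z = pd.DataFrame(Z, index=sub.index, columns=sub.columns)
    names = list(sub.index)
    nc_names = [n for n, keep in zip(names, nc) if keep]
    const_names = [n for n, keep in zip(names, nc) if not keep]
    if len(nc_names) > 1:
        link = average(pdist(Z[nc], metric="euclidean"))
        ordered = [nc_names[i] for i in leaves_list(link)]
    else:
        ordered = nc_names
    row_order = ordered + const_names
    return ZHeatmap(matrix=z.loc[row_order], row_order=row_order)


FAMILY_GROUPS = {"His-GUG": "HisGUG", "Lys-CUU": "LysCUU"}


def family_group(family_id: str) -> str:
    """Volcano color group: HisGUG, LysCUU or other."""
    return FAMILY_GROUPS.get(family_id, "other")


def volcano_table(
    de: pd.DataFrame,
    padj_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Annotated volcano rows; fragments with NA padj are excluded."""
    na = de["padj"].isna()
    if na.any():
        logger.info("volcano: excluding %d fragments with NA padj", int(na.sum()))
    d = de[~na].copy()
    out = pd.DataFrame(
        dict(
            fragment=d.index,
            family_group=[family_group(f.split(":", 1)[0]) for f in d.index],
            log2fc=d["log2fc"].to_numpy(),
            padj=d["padj"].to_numpy(),
            neg_log10_padj=-np.log10(d["padj"].to_numpy()),
            significant=significant(d, padj_cutoff, lfc_cutoff).to_numpy(),
        )
    )
    return out.reset_index(drop=True)


def family_trends(norm_counts: pd.DataFrame, design: DesignInfo) -> pd.DataFrame:
    """Per-family normalized totals per sample plus per-timepoint means.

    ``norm_counts`` is the fragment x sample matrix (index
    "family_id:name") divided by size factors.
    """
    fam = pd.Series([f.split(":", 1)[0] for f in norm_counts.index], index=norm_counts.index)
    totals = norm_counts.groupby(fam).sum()
    out = totals.copy()
    for tp in design.timepoint_order:
        out[f"mean_{tp}"] = totals[design.samples_at(tp)].mean(axis=1)
    out.insert(0, "family_id", totals.index)
    return out.reset_index(drop=True)


# -- optional thin plotting layer ------------------------------------------

def plot_volcano(vt: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"HisGUG": "red", "LysCUU": "green", "other": "grey"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, sub in vt.groupby("family_group"):
        ax.scatter(sub["log2fc"], sub["neg_log10_padj"], s=8,
                   c=colors.get(grp, "grey"), label=grp, alpha=0.7)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_pca(proj: PCAProjection, design: DesignInfo, path: str | Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    tps = design.timepoint_order
    cmap = dict(zip(tps, ["#1b9e77", "#d95f02", "#7570b3", "#e7298a"]))
    for tp in tps:
        rows = proj.coordinates.loc[design.samples_at(tp)]
        ax.scatter(rows["PC1"], rows["PC2"], label=tp, c=cmap.get(tp, "black"))
    evr = proj.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_heatmap(hm: ZHeatmap, path: str | Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import seaborn as sns
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, max(3, 0.25 * hm.matrix.shape[0])))
    sns.heatmap(hm.matrix, cmap="vlag", center=0, ax=ax,
                yticklabels=True, cbar_kws={"label": "z-score"})
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
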