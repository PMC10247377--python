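"""Single-cell stage: genotype-to-phenotype linkage.

Four pieces work off one cell × gene count matrix (an :class:`anndata.AnnData`
with ``obs`` carrying sample/day/barcode and ``var`` carrying gene genomic
positions):

* expression-based per-cell copy-number inference — a moving-average log
  ratio versus a diploid reference along the genome, summarized to arm-level
  calls and per-barcode consensus karyotypes;
* LSI (TF-IDF + truncated SVD) embedding of a labeled reference with
  out-of-sample projection of query cells and k-nearest-neighbour cell-type
  frequencies (default k = 25);
* per-gene two-sided Wilcoxon rank-sum differential expression with
  Bonferroni control, and cross-culture intersections of significant sets;
* gene-set enrichment via the two-sample Kolmogorov–Smirnov statistic on
  ranks with Benjamini–Hochberg adjustment across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.ndimage import uniform_filter1d
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .genome import GenomeModel

__all__ = [
    "CellCNAMatrix",
    "ReferenceModel",
    "qc_filter",
    "infer_cell_cna",
    "link_barcode_cna",
    "fit_reference",
    "project_cells",
    "knn_type_frequencies",
    "deg_wilcoxon",
    "intersect_degs",
    "gsea_ks",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)


def _cp10k(X) -> np.ndarray:
    X = _dense(X).astype(float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return X / totals * 1e4


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    adata,
    min_counts: int = 500,
    min_genes: int = 200,
    max_mito_fraction: float = 0.2,
):
    """Remove cells failing any threshold; returns (filtered AnnData, report).

    Mitochondrial content is measured on genes named ``MT-*`` (zero when none
    are present). The report records retained/removed counts per criterion.
    """
    X = _dense(adata.X)
    total = X.sum(axis=1)
    n_genes = (X > 0).sum(axis=1)
    mito_mask = np.array([str(g).startswith("MT-") for g in adata.var_names])
    mito_frac = (
        X[:, mito_mask].sum(axis=1) / np.maximum(total, 1) if mito_mask.any()
        else np.zeros(len(total))
    )
    ok = (total >= min_counts) & (n_genes >= min_genes) & (mito_frac <= max_mito_fraction)
    if not ok.any():
        raise ValueError("quality control removed every cell")
    report = {
        "n_input": int(len(ok)),
        "n_retained": int(ok.sum()),
        "n_removed": int((~ok).sum()),
        "removed_low_counts": int((total < min_counts).sum()),
        "removed_few_genes": int((n_genes < min_genes).sum()),
        "removed_high_mito": int((mito_frac > max_mito_fraction).sum()),
    }
    return adata[ok].copy(), report


# ---------------------------------------------------------------------------
# expression-based CNA inference
# ---------------------------------------------------------------------------


@dataclass
class CellCNAMatrix:
    """Smoothed relative-expression log ratios with arm-level calls."""

    smoothed: pd.DataFrame       # cells × genes (genome order), centered
    arm_means: pd.DataFrame      # cells × arms (NaN = uncallable arm)
    arm_calls: pd.DataFrame      # cells × arms in {-1, 0, +1} (NaN uncallable)
    consensus: pd.DataFrame      # barcode × arms, majority call; barcodes ≥ min_cells
    cell_barcodes: pd.Series     # barcode per cell (−1 = unassigned)
    arm_threshold: float


def _order_genes(var: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    chrom_rank = {c.name: i for i, c in enumerate(genome.chromosomes)}
    v = var[var["chrom"].isin(chrom_rank)].copy()
    v["_rank"] = v["chrom"].map(chrom_rank)
    v = v.sort_values(["_rank", "start"], kind="stable").drop(columns="_rank")
    cent = {c.name: c.centromere for c in genome.chromosomes}
    v["arm"] = [
        f"{c}{'p' if s < cent[c] else 'q'}" for c, s in zip(v["chrom"], v["start"])
    ]
    return v


def infer_cell_cna(
    adata,
    reference,
    genome: GenomeModel,
    window_genes: int = 101,
    arm_threshold: float = 0.1,
    min_cells: int = 10,
    pseudocount: float = 1.0,
) -> CellCNAMatrix:
    """Arm-level copy-number calls per cell from expression dosage.

    Depth-normalized expression is compared against the reference-cell mean
    per gene (log2 ratio), smoothed along the genome with a centered moving
    average of ``window_genes`` genes per chromosome, median-centered per cell
    and re-centered on the reference cells so that diploid arms sit at 0.
    An arm with fewer than ``window_genes / 2`` measured genes is marked
    uncallable (NaN). Per-barcode consensus calls (majority over cells) are
    emitted only for barcodes with at least ``min_cells`` cells.
    """
    if reference.n_obs < 50:
        raise ValueError("need at least 50 reference cells")
    var = _order_genes(adata.var, genome)
    genes = var.index.to_numpy()
    if len(genes) == 0:
        raise ValueError("no genes with genomic positions on the genome model")
    shared = [g for g in genes if g in set(reference.var_names)]
    var = var.loc[shared]
    genes = var.index.to_numpy()

    q = _cp10k(adata[:, genes].X)
    r = _cp10k(reference[:, genes].X)
    ref_mean = r.mean(axis=0)
    lr_q = np.log2((q + pseudocount) / (ref_mean + pseudocount))
    lr_r = np.log2((r + pseudocount) / (ref_mean + pseudocount))

    def smooth(mat: np.ndarray) -> np.ndarray:
        out = np.empty_like(mat)
        for chrom in dict.fromkeys(var["chrom"]):
            cols = np.flatnonzero((var["chrom"] == chrom).to_numpy())
            w = min(window_genes, len(cols))
            if w % 2 == 0:
                w -= 1
            w = max(w, 1)
            out[:, cols] = uniform_filter1d(mat[:, cols], size=w, axis=1, mode="nearest")
        return out

    sm_q = smooth(lr_q)
    sm_r = smooth(lr_r)
    sm_q -= np.median(sm_q, axis=1, keepdims=True)
    sm_r -= np.median(sm_r, axis=1, keepdims=True)
    ref_center = sm_r.mean(axis=0)
    sm_q -= ref_center

    arms = [a for a in genome.arms if a in set(var["arm"])]
    arm_means = pd.DataFrame(index=adata.obs_names, columns=arms, dtype=float)
    for arm in arms:
        cols = np.flatnonzero((var["arm"] == arm).to_numpy())
        if len(cols) < window_genes / 2:
            arm_means[arm] = np.nan
        else:
            arm_means[arm] = sm_q[:, cols].mean(axis=1)
    calls = pd.DataFrame(
        np.where(
            arm_means.isna(), np.nan,
            np.sign(arm_means.to_numpy()) * (np.abs(arm_means.to_numpy()) >= arm_threshold),
        ),
        index=arm_means.index,
        columns=arm_means.columns,
    )

    barcodes = (
        adata.obs["barcode_id"]
        if "barcode_id" in adata.obs
        else pd.Series(-1, index=adata.obs_names)
    )
    consensus_rows = {}
    for bc, group in calls.groupby(barcodes):
        if int(bc) < 0 or len(group) < min_cells:
            continue
        row = {}
        for arm in arms:
            col = group[arm].dropna()
            if col.empty:
                row[arm] = np.nan
                continue
            counts = col.value_counts()
            top = counts.index[np.argsort(-counts.to_numpy(), kind="stable")[0]]
            row[arm] = float(top) if counts[top] > len(col) / 2 else 0.0
        consensus_rows[int(bc)] = row
    consensus = pd.DataFrame.from_dict(consensus_rows, orient="index", columns=arms)
    consensus.index.name = "barcode_id"

    return CellCNAMatrix(
        smoothed=pd.DataFrame(sm_q, index=adata.obs_names, columns=genes),
        arm_means=arm_means,
        arm_calls=calls,
        consensus=consensus.sort_index(),
        cell_barcodes=pd.Series(np.asarray(barcodes), index=adata.obs_names),
        arm_threshold=arm_threshold,
    )


def link_barcode_cna(cc: CellCNAMatrix, bulk) -> dict:
    """Concordance of the cell-population CNA consensus with a bulk profile.

    The population call per arm is the cell-frequency-weighted majority over
    per-cell calls; agreement with the bulk arm calls is reported per arm and
    as a Jaccard index over called events.
    """
    calls = cc.arm_calls
    arms = [a for a in calls.columns if not calls[a].isna().all()]
    pop_events: set[str] = set()
    rows = []
    bulk_events = {e for e in bulk.present_events() if e[:-1] in set(calls.columns)}
    for arm in arms:
        col = calls[arm].dropna()
        frac_gain = float((col == 1).mean())
        frac_loss = float((col == -1).mean())
        call = "gain" if frac_gain > 0.5 else ("loss" if frac_loss > 0.5 else "neutral")
        if call != "neutral":
            pop_events.add(f"{arm}{'+' if call == 'gain' else '-'}")
        bulk_call = (
            "gain" if f"{arm}+" in bulk_events
            else ("loss" if f"{arm}-" in bulk_events else "neutral")
        )
        rows.append(
            {
                "arm": arm,
                "cell_call": call,
                "bulk_call": bulk_call,
                "agree": call == bulk_call,
                "cell_gain_fraction": frac_gain,
                "cell_loss_fraction": frac_loss,
            }
        )
    union = pop_events | bulk_events
    jaccard = len(pop_events & bulk_events) / len(union) if union else 1.0
    return {"table": pd.DataFrame(rows), "jaccard": float(jaccard),
            "cell_events": pop_events, "bulk_events": bulk_events}


# ---------------------------------------------------------------------------
# LSI reference projection + kNN label transfer
# ---------------------------------------------------------------------------


@dataclass
class ReferenceModel:
    """Fitted LSI embedding of a labeled reference with projection weights."""

    genes: np.ndarray
    idf: np.ndarray
    svd: TruncatedSVD
    coordinates: np.ndarray      # reference cells × n_dims, L2-normalized
    labels: np.ndarray
    cell_names: np.ndarray


def _tfidf(X: np.ndarray, idf: np.ndarray) -> np.ndarray:
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    tf = X / totals
    return np.log1p(tf * 1e4) * idf


def _l2(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def fit_reference(
    reference,
    labels: pd.Series | np.ndarray,
    n_dims: int = 30,
    n_top_genes: int = 2000,
    random_state: int = 0,
) -> ReferenceModel:
    """LSI model of a labeled reference: TF-IDF, truncated SVD, L2-normalize.

    The ``n_top_genes`` most variable genes (log1p CP10K variance) form the
    vocabulary; the stored IDF weights and SVD loadings project query cells
    out of sample without refitting.
    """
    labels = np.asarray(labels)
    if len(labels) != reference.n_obs:
        raise ValueError("labels must cover all reference cells")
    if len(set(labels)) < 2:
        warnings.warn("reference has a single cell type", stacklevel=2)
    X = _dense(reference.X)
    var = np.log1p(_cp10k(X)).var(axis=0)
    n_top = min(n_top_genes, X.shape[1])
    top = np.sort(np.argsort(-var, kind="stable")[:n_top])
    genes = np.asarray(reference.var_names)[top]
    Xt = X[:, top]
    df_gene = (Xt > 0).sum(axis=0)
    idf = np.log1p(Xt.shape[0] / (1.0 + df_gene))
    M = _tfidf(Xt, idf)
    if n_dims >= min(M.shape):
        raise ValueError(f"n_dims={n_dims} must be below the matrix rank bound {min(M.shape)}")
    svd = TruncatedSVD(n_components=n_dims, random_state=random_state)
    coords = _l2(svd.fit_transform(M))
    return ReferenceModel(
        genes=genes,
        idf=idf,
        svd=svd,
        coordinates=coords,
        labels=labels,
        cell_names=np.asarray(reference.obs_names),
    )


def project_cells(model: ReferenceModel, query) -> tuple[np.ndarray, float]:
    """Project query cells into the reference embedding; returns (coords, shared).

    Query genes are matched to the model vocabulary by name; vocabulary genes
    absent from the query contribute zeros. ``shared`` is the proportion of
    the vocabulary found in the query. Projection of a reference cell through
    its own model reproduces the stored coordinates.
    """
    qgenes = {g: i for i, g in enumerate(query.var_names)}
    cols = [qgenes.get(g, -1) for g in model.genes]
    shared = float(np.mean([c >= 0 for c in cols]))
    if shared == 0:
        raise ValueError("query shares no genes with the reference vocabulary")
    Xq = _dense(query.X)
    M = np.zeros((query.n_obs, len(model.genes)))
    present = [i for i, c in enumerate(cols) if c >= 0]
    M[:, present] = Xq[:, [cols[i] for i in present]]
    coords = _l2(model.svd.transform(_tfidf(M, model.idf)))
    return coords, shared


def knn_type_frequencies(
    coords: np.ndarray,
    model: ReferenceModel,
    k: int = 25,
    samples: pd.Series | np.ndarray | None = None,
    majority_vote: bool = False,
) -> pd.DataFrame:
    """Cell-type frequencies from the k nearest reference neighbours (k = 25).

    Each query cell's neighbours vote; per-sample frequencies average the
    per-cell label fractions (or, with ``majority_vote``, assign each cell its
    plurality label first). Rows sum to 1.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(model.coordinates):
        raise ValueError("k exceeds the number of reference cells")
    nn = NearestNeighbors(n_neighbors=k).fit(model.coordinates)
    _, idx = nn.kneighbors(coords)
    types = sorted(set(model.labels))
    fractions = np.zeros((len(coords), len(types)))
    for t_i, t in enumerate(types):
        fractions[:, t_i] = (model.labels[idx] == t).mean(axis=1)
    if majority_vote:
        arg = fractions.argmax(axis=1)
        fractions = np.zeros_like(fractions)
        fractions[np.arange(len(coords)), arg] = 1.0
    cell_table = pd.DataFrame(fractions, columns=types)
    if samples is None:
        samples = pd.Series("all", index=cell_table.index)
    cell_table["sample"] = np.asarray(samples)
    out = cell_table.groupby("sample").mean()
    out.index.name = "sample"
    return out


# ---------------------------------------------------------------------------
# differential expression + enrichment
# ---------------------------------------------------------------------------


def deg_wilcoxon(group_a, group_b) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE per gene with Bonferroni control.

    Inputs are AnnData views over the same genes. Tests run on
    depth-normalized log counts: exact p-values below 10 cells per group
    (ties permitting), the tie-corrected normal approximation otherwise.
    A gene constant across both groups gets p = 1. ``direction`` is +1 when
    group A is higher.
    """
    if group_a.n_obs < 3 or group_b.n_obs < 3:
        raise ValueError("need at least three cells per group")
    if list(group_a.var_names) != list(group_b.var_names):
        raise ValueError("groups must share one gene vocabulary")
    A = np.log1p(_cp10k(group_a.X))
    B = np.log1p(_cp10k(group_b.X))
    n_genes = A.shape[1]
    small = min(A.shape[0], B.shape[0]) < 10
    p = np.ones(n_genes)
    for j in range(n_genes):
        a, b = A[:, j], B[:, j]
        combined = np.concatenate([a, b])
        if np.all(combined == combined[0]):
            continue
        has_ties = len(np.unique(combined)) < len(combined)
        method = "exact" if (small and not has_ties) else "asymptotic"
        p[j] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    direction = np.sign(A.mean(axis=0) - B.mean(axis=0)).astype(int)
    p_bonf = np.minimum(p * n_genes, 1.0)
    return pd.DataFrame(
        {
            "gene": np.asarray(group_a.var_names),
            "direction": direction,
            "p": p,
            "p_bonferroni": p_bonf,
            "significant": p_bonf < 0.05,
        }
    ).set_index("gene")


def intersect_degs(per_culture: dict[str, pd.DataFrame]) -> dict:
    """Genes consistently significant across cultures, by direction.

    Input: culture → deg_wilcoxon table. Output: shared up/down gene sets
    plus the full UpSet membership table (one row per gene observed as
    significant anywhere, boolean membership per culture and direction).
    """
    if len(per_culture) < 2:
        raise ValueError("need at least two cultures")
    ups, downs = {}, {}
    for culture, table in per_culture.items():
        sig = table[table["significant"]]
        ups[culture] = set(sig.index[sig["direction"] > 0])
        downs[culture] = set(sig.index[sig["direction"] < 0])
    shared_up = set.intersection(*ups.values())
    shared_down = set.intersection(*downs.values())
    all_genes = sorted(set().union(*ups.values(), *downs.values()))
    rows = []
    for g in all_genes:
        row = {"gene": g}
        for culture in per_culture:
            row[f"{culture}_up"] = g in ups[culture]
            row[f"{culture}_down"] = g in downs[culture]
        rows.append(row)
    upset = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
    return {"shared_up": shared_up, "shared_down": shared_down, "upset": upset}


def gsea_ks(
    scores: pd.Series, gene_sets: dict[str, list[str]], min_size: int = 5
) -> pd.DataFrame:
    """KS-statistic gene-set enrichment with Benjamini–Hochberg adjustment.

    ``scores`` rank genes (higher = up). Each set's in-set ranks are compared
    with the out-of-set ranks by a two-sided two-sample KS test (exact below
    20 members, asymptotic otherwise); direction is the sign of the mean rank
    shift. Sets with fewer than ``min_size`` members in the ranking are
    skipped with a warning.
    """
    ranks = scores.rank(method="average")
    rows = []
    for name, members in gene_sets.items():
        in_set = ranks.loc[[g for g in members if g in ranks.index]]
        if len(in_set) < min_size:
            warnings.warn(
                f"gene set {name}: only {len(in_set)} members in the ranking; skipped",
                stacklevel=2,
            )
            continue
        out_set = ranks.drop(in_set.index)
        if len(out_set) == 0:
            # the set spans the entire ranking: identical distributions
            rows.append({"set": name, "n": len(in_set), "score": 0.0,
                         "direction": "up", "p": 1.0})
            continue
        method = "exact" if len(in_set) < 20 else "asymp"
        res = stats.ks_2samp(in_set, out_set, alternative="two-sided", method=method)
        rows.append(
            {
                "set": name,
                "n": len(in_set),
                "score": float(res.statistic),
                "direction": "up" if in_set.mean() > out_set.mean() else "down",
                "p": float(res.pvalue),
            }
        )
    table = pd.DataFrame(rows, columns=["set", "n", "score", "direction", "p"])
    if len(table):
        table["p_bh"] = stats.false_discovery_control(table["p"], method="bh")
    else:
        table["p_bh"] = []
    return table.set_index("set")
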