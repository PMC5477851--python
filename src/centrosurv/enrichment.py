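"""Gene-set enrichment analysis of high- vs low-expression phenotypes.

Genes are ranked by a signal-to-noise metric between the two phenotype
classes; each gene set's enrichment score (ES) is the signed maximal
deviation of a weighted Kolmogorov-Smirnov running sum over the ranked
list; the null distribution comes from phenotype-label permutations,
which also yield the normalized enrichment score (NES), a nominal
permutation p-value, and a pooled same-sign FDR q-value.  A set is
flagged significant at FDR q < 0.25 with nominal p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .survival import optimal_cutpoint

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "stratify_by_gene",
    "rank_genes",
    "signal_to_noise",
    "enrichment_score",
    "GSEA",
    "gsea",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {line_no}: GMT rows need name, "
                    "description and at least one member"
                )
            members = frozenset(g for g in parts[2:] if g)
            sets.append(GeneSet(parts[0], members, parts[1]))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(path, gene_sets) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description or "na"]
                               + sorted(gs.members)) + "\n")


def stratify_by_gene(matrix: pd.DataFrame, clinical: pd.DataFrame | None,
                     gene: str = "KIFC1",
                     cutpoint_source: str = "survival_optimal",
                     min_group_frac: float = 0.10, seed=None) -> pd.Series:
    """Binary high/low phenotype labels for each sample.

    ``survival_optimal`` places samples below the gene's optimal overall
    survival cut-point (maximal log-rank chi-square) in the low group and
    the rest in the high group; ``median`` splits at the sample median.
    """
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    values = matrix.loc[gene]
    if values.nunique() < 2:
        raise ValueError(f"gene {gene!r} is constant: no valid split")
    if cutpoint_source == "median":
        thr = float(values.median())
        labels = np.where(values > thr, "high", "low")
        # even split on even n: push exact-median samples to low
    elif cutpoint_source == "survival_optimal":
        if clinical is None:
            raise ValueError("survival_optimal stratification needs clinical data")
        clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
            else clinical
        clin = clin.loc[[s for s in matrix.columns if s in clin.index]]
        clin = clin.dropna(subset=["os_months", "event"])
        if clin.empty:
            raise ValueError("no overall-survival data available for stratification")
        marker = values.loc[clin.index].to_numpy(dtype=float)
        cut = optimal_cutpoint(marker, clin["os_months"].to_numpy(),
                               clin["event"].to_numpy(),
                               min_group_frac=min_group_frac, seed=seed)
        labels = np.where(values > cut.threshold, "high", "low")
    else:
        raise ValueError("cutpoint_source must be 'survival_optimal' or 'median'")
    return pd.Series(labels, index=matrix.columns, name=f"{gene}_group")


def signal_to_noise(high: np.ndarray, low: np.ndarray,
                    sd_floor_frac: float = 0.2,
                    sd_floor_abs: float = 0.2) -> np.ndarray:
    """(mu_high - mu_low) / (sigma_high + sigma_low) per gene (rows).

    Each class SD is floored at ``sd_floor_frac * |class mean|``; if that
    floor is itself zero (mean 0) the absolute floor applies.  This keeps
    low-variance genes from dominating the ranking.
    """
    mh, ml = high.mean(axis=1), low.mean(axis=1)
    sh = high.std(axis=1, ddof=1)
    sl = low.std(axis=1, ddof=1)

    def _floor(s, m):
        fl = sd_floor_frac * np.abs(m)
        fl = np.where(fl == 0, sd_floor_abs, fl)
        return np.maximum(s, fl)

    return (mh - ml) / (_floor(sh, mh) + _floor(sl, ml))


def _t_stat(high, low):
    mh, ml = high.mean(axis=1), low.mean(axis=1)
    vh = high.var(axis=1, ddof=1) / high.shape[1]
    vl = low.var(axis=1, ddof=1) / low.shape[1]
    denom = np.sqrt(vh + vl)
    denom = np.where(denom == 0, 1e-12, denom)
    return (mh - ml) / denom


_METRICS = {"signal_to_noise": signal_to_noise, "t_stat": _t_stat}


def _metric_values(X: np.ndarray, high_mask: np.ndarray, metric: str):
    if high_mask.sum() < 2 or (~high_mask).sum() < 2:
        raise ValueError("each phenotype class needs at least 2 samples")
    return _METRICS[metric](X[:, high_mask], X[:, ~high_mask])


def rank_genes(matrix: pd.DataFrame, labels, metric: str = "signal_to_noise"
               ) -> pd.DataFrame:
    """Rank genes by class-separation metric, descending.

    Ties are broken deterministically by gene id (ascending) so the
    ordering is strict.  Returns a DataFrame with columns gene, metric.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    labels = pd.Series(labels, index=matrix.columns) \
        if not isinstance(labels, pd.Series) else labels
    high = (labels.loc[matrix.columns] == "high").to_numpy()
    vals = _metric_values(matrix.to_numpy(dtype=float), high, metric)
    out = pd.DataFrame({"gene": matrix.index.astype(str), "metric": vals})
    return out.sort_values(["metric", "gene"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


def enrichment_score(gene_ids, metric_values, gene_set,
                     weight_p: float = 1.0):
    """Weighted KS running-sum enrichment score.

    At each position down the ranked list the sum increments by
    ``|metric|^p / sum(|metric|^p over hits)`` on a gene-set hit and
    decrements by ``1/(N - N_hits)`` on a miss; the ES is the running-sum
    value of maximal absolute deviation from zero.  Returns
    ``(es, running_sum)``.
    """
    genes = np.asarray(list(gene_ids))
    r = np.asarray(metric_values, dtype=float)
    if genes.size != r.size:
        raise ValueError("gene ids and metric values must align")
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    hit = np.isin(genes, list(members))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hits == genes.size:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(r) ** weight_p
    denom = w[hit].sum()
    if denom == 0:
        # all hit metrics are exactly zero: fall back to unweighted hits
        w = np.ones_like(w)
        denom = float(n_hits)
    steps = np.where(hit, w / denom, -1.0 / (genes.size - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


class GSEA(BaseEstimator):
    """Phenotype-permutation gene-set enrichment analysis.

    ``fit(X, y)`` takes ``X`` as a samples x genes DataFrame and ``y``
    as 'high'/'low' labels.  After fitting, ``results_`` holds one row
    per gene set with es, nes, p_nominal, fdr_q, leading-edge genes and
    the significance flag; ``running_sums_`` maps set name to its
    running-sum trace.

    NES normalizes each ES by the mean absolute same-sign permuted ES of
    its own set; FDR q pools same-sign permuted NES over all sets.
    """

    def __init__(self, gene_sets=(), n_permutations: int = 1000,
                 weight_p: float = 1.0, metric: str = "signal_to_noise",
                 random_state=None):
        self.gene_sets = gene_sets
        self.n_permutations = n_permutations
        self.weight_p = weight_p
        self.metric = metric
        self.random_state = random_state

    def fit(self, X, y):
        gene_sets = list(self.gene_sets)
        if not gene_sets:
            raise ValueError("no gene sets supplied")
        if self.n_permutations < 100:
            warnings.warn(
                f"n_permutations={self.n_permutations} is small; p-values "
                "and FDR q will be coarse"
            )
        if isinstance(X, pd.DataFrame):
            genes = np.asarray(X.columns.astype(str))
            Xg = X.to_numpy(dtype=float).T   # genes x samples
        else:
            raise TypeError("X must be a samples x genes DataFrame")
        y = np.asarray(y)
        high = y == "high"
        if high.sum() < 2 or (~high).sum() < 2:
            raise ValueError("each phenotype class needs at least 2 samples")

        def ranked_es(mask):
            vals = _metric_values(Xg, mask, self.metric)
            order = np.lexsort((genes, -vals))
            g_sorted, v_sorted = genes[order], vals[order]
            out = []
            for gs in gene_sets:
                es, run = enrichment_score(g_sorted, v_sorted, gs,
                                           self.weight_p)
                out.append((es, run, g_sorted, v_sorted))
            return out

        obs = ranked_es(high)
        es_obs = np.array([o[0] for o in obs])

        rng = np.random.default_rng(self.random_state)
        B = int(self.n_permutations)
        es_perm = np.empty((B, len(gene_sets)))
        for b in range(B):
            perm_mask = np.zeros(high.size, dtype=bool)
            perm_mask[rng.choice(high.size, size=int(high.sum()),
                                 replace=False)] = True
            vals = _metric_values(Xg, perm_mask, self.metric)
            order = np.lexsort((genes, -vals))
            g_sorted, v_sorted = genes[order], vals[order]
            for k, gs in enumerate(gene_sets):
                es_perm[b, k], _ = enrichment_score(
                    g_sorted, v_sorted, gs, self.weight_p)

        nes_obs = np.empty(len(gene_sets))
        p_nom = np.empty(len(gene_sets))
        nes_perm = np.full_like(es_perm, np.nan)
        for k in range(len(gene_sets)):
            col = es_perm[:, k]
            for sign in (1.0, -1.0):
                same = col * sign > 0
                mean_abs = np.abs(col[same]).mean() if same.any() else np.nan
                if np.isfinite(mean_abs) and mean_abs > 0:
                    nes_perm[same, k] = col[same] / mean_abs
            es = es_obs[k]
            same = col * np.sign(es) > 0 if es != 0 else np.ones(B, bool)
            n_same = int(same.sum())
            if es >= 0:
                p_nom[k] = ((col[same] >= es).sum() + 1) / (n_same + 1) \
                    if n_same else 1.0
                mean_abs = col[same].mean() if n_same else np.nan
            else:
                p_nom[k] = ((col[same] <= es).sum() + 1) / (n_same + 1) \
                    if n_same else 1.0
                mean_abs = np.abs(col[same]).mean() if n_same else np.nan
            nes_obs[k] = es / mean_abs if np.isfinite(mean_abs) and mean_abs > 0 \
                else np.nan

        fdr = self._fdr_q(nes_obs, nes_perm)

        rows = []
        self.running_sums_ = {}
        for k, gs in enumerate(gene_sets):
            es, run, g_sorted, v_sorted = obs[k]
            peak = int(np.argmax(np.abs(run)))
            in_set = np.isin(g_sorted, list(gs.members))
            if es >= 0:
                leading = g_sorted[: peak + 1][in_set[: peak + 1]]
            else:
                leading = g_sorted[peak:][in_set[peak:]]
            rows.append({
                "set_name": gs.name,
                "size": int(in_set.sum()),
                "es": es,
                "nes": nes_obs[k],
                "p_nominal": p_nom[k],
                "fdr_q": fdr[k],
                "leading_edge": ",".join(leading.tolist()),
                "significant": bool(fdr[k] < 0.25 and p_nom[k] < 0.05),
            })
            self.running_sums_[gs.name] = run
        self.results_ = pd.DataFrame(rows).sort_values(
            "nes", ascending=False, na_position="last").reset_index(drop=True)
        self.es_permutations_ = es_perm
        return self

    @staticmethod
    def _fdr_q(nes_obs, nes_perm):
        """Pooled same-sign FDR: for each observed NES, the ratio of the
        permuted tail fraction to the observed tail fraction, capped at 1
        and made monotone in |NES|."""
        pool = nes_perm[np.isfinite(nes_perm)]
        obs = nes_obs[np.isfinite(nes_obs)]
        q = np.full(nes_obs.shape, np.nan)
        for k, nes in enumerate(nes_obs):
            if not np.isfinite(nes):
                continue
            if nes >= 0:
                num_pool = pool[pool >= 0]
                num = (num_pool >= nes).mean() if num_pool.size else 1.0
                den_obs = obs[obs >= 0]
                den = (den_obs >= nes).mean() if den_obs.size else 1.0
            else:
                num_pool = pool[pool < 0]
                num = (num_pool <= nes).mean() if num_pool.size else 1.0
                den_obs = obs[obs < 0]
                den = (den_obs <= nes).mean() if den_obs.size else 1.0
            q[k] = min(1.0, num / den) if den > 0 else 1.0
        # enforce monotone non-increasing q in |NES| within each sign
        for sign_mask in (nes_obs >= 0, nes_obs < 0):
            idx = np.where(sign_mask & np.isfinite(nes_obs))[0]
            if idx.size:
                order = idx[np.argsort(-np.abs(nes_obs[idx]))]
                q[order] = np.minimum.accumulate(q[order])
        return q


def gsea(matrix: pd.DataFrame, labels, gene_sets, n_permutations: int = 1000,
         weight_p: float = 1.0, seed=None) -> pd.DataFrame:
    """Run GSEA on a genes x samples matrix; thin wrapper over :class:`GSEA`."""
    est = GSEA(gene_sets=gene_sets, n_permutations=n_permutations,
               weight_p=weight_p, random_state=seed)
    est.fit(matrix.T, np.asarray(pd.Series(labels)))
    return est.results_
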