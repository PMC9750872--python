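"""Gene-level scoring of sgRNA phenotypes and discriminant hit calling.

Per gene (per TSS first, for multi-TSS libraries):

- phenotype = mean of the top-3 sgRNA phenotypes by absolute value (signed
  values are averaged; fewer than 3 available -> mean of all);
- p-value = two-sided Mann-Whitney U of *all* the gene's sgRNA phenotypes vs
  all non-targeting sgRNA phenotypes;
- z = (phenotype - mu_NCG) / sigma_NCG, where mu/sigma are the mean and
  standard deviation of the collapsed phenotypes of negative-control
  pseudo-genes (random groups of non-targeting sgRNAs scored identically);
- discriminant = |z| * -log10(p); a gene is a hit when the discriminant
  reaches the threshold (default 7), on either side (sensitizing rho < 0,
  protective rho > 0).

Genes with multiple TSSs are collapsed to the TSS with the lowest
Mann-Whitney p-value, that row retained verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import SgRNALibrary
from .stats import bh_fdr, rank_sum_p

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "gene", "tss", "phenotype", "p_value", "z", "discriminant",
    "n_sgrnas_used", "is_hit", "direction", "bh_fdr",
]


def collapse_gene(phenotypes, sgrna_ids=None, k: int = 3) -> float:
    """Mean of the ``k`` phenotypes of largest absolute value (signed average).

    Fewer than ``k`` values -> mean of all. Ties in absolute value are broken
    by sgrna_id lexicographic order so the collapse is deterministic.
    """
    vals = np.asarray(phenotypes, dtype=float)
    vals = vals[~np.isnan(vals)] if sgrna_ids is None else vals
    if sgrna_ids is not None:
        ids = np.asarray(sgrna_ids, dtype=object)
        keep = ~np.isnan(vals)
        vals, ids = vals[keep], ids[keep]
    if vals.size == 0:
        return np.nan
    if sgrna_ids is None:
        order = np.lexsort((-np.abs(vals),))
    else:
        order = np.lexsort((ids, -np.abs(vals)))
    return float(np.mean(vals[order[:k]]))


@dataclass(frozen=True)
class NegativeControlGeneSet:
    """Pseudo-genes: random groups of non-targeting sgRNA ids, each scored like
    a real gene to calibrate z-scores and empirical false-positive rates."""

    groups: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def size(self) -> int:
        return len(self.groups[0]) if self.groups else 0

    def __len__(self) -> int:
        return len(self.groups)


def make_negative_control_genes(
    library: SgRNALibrary, n_pseudo: int, size: int, seed: int = 0
) -> NegativeControlGeneSet:
    """Sample ``n_pseudo`` groups of ``size`` non-targeting sgRNAs.

    Members are drawn without replacement within a group, independently
    across groups; exact duplicate member sets are resampled. Deterministic
    under ``seed``.
    """
    nt = library.nontargeting_ids
    if size > len(nt):
        raise ValueError(
            f"pseudo-gene size {size} exceeds the {len(nt)} non-targeting sgRNAs"
        )
    rng = np.random.default_rng(seed)
    nt_arr = np.array(nt, dtype=object)
    seen: set[frozenset[str]] = set()
    groups: list[tuple[str, ...]] = []
    attempts = 0
    while len(groups) < n_pseudo:
        members = tuple(rng.choice(nt_arr, size=size, replace=False))
        key = frozenset(members)
        attempts += 1
        if key in seen:
            if attempts > 100 * n_pseudo + 100:
                raise ValueError(
                    "cannot draw distinct pseudo-genes: member-set space exhausted"
                )
            continue
        seen.add(key)
        groups.append(members)
    return NegativeControlGeneSet(tuple(groups), seed)


@dataclass
class GeneScoreResult:
    """Scored screen: per-TSS and TSS-collapsed gene tables plus pseudo-gene
    calibration scores and the NCG moments used for z."""

    per_tss: pd.DataFrame
    collapsed: pd.DataFrame
    pseudo: pd.DataFrame
    mu_ncg: float
    sigma_ncg: float
    threshold: float
    metric: str

    @property
    def hits(self) -> pd.DataFrame:
        return self.collapsed.loc[self.collapsed["is_hit"]]

    def write(self, path: str | Path) -> None:
        self.collapsed.to_csv(path, sep="\t", index=False)


def _score_groups(
    groups: list[tuple[str, str, np.ndarray, np.ndarray]],
    nt_values: np.ndarray,
    k: int,
) -> pd.DataFrame:
    rows = []
    for gene, tss, ids, vals in groups:
        keep = ~np.isnan(vals)
        n_used = int(keep.sum())
        if n_used == 0:
            logger.warning("gene %s/%s: no unfiltered sgRNAs; score missing", gene, tss)
            rows.append((gene, tss, np.nan, np.nan, n_used))
            continue
        phen = collapse_gene(vals[keep], ids[keep], k=k)
        p = rank_sum_p(vals[keep], nt_values)
        rows.append((gene, tss, phen, p, n_used))
    return pd.DataFrame(
        rows, columns=["gene", "tss", "phenotype", "p_value", "n_sgrnas_used"]
    )


def score_genes(
    phenotypes: pd.DataFrame,
    ncg: NegativeControlGeneSet,
    metric: str = "rho",
    threshold: float = 7.0,
    top_k: int = 3,
) -> GeneScoreResult:
    """Score every gene/TSS group of a phenotype table and call hits.

    ``phenotypes`` is the per-sgRNA table from :mod:`chemscreen.phenotype`
    (columns sgrna_id, gene, tss, is_nontargeting and the chosen metric).
    Pseudo-genes from ``ncg`` are scored with the identical procedure; their
    collapsed-phenotype mean/SD define the z-score. Raises when the
    pseudo-gene SD is 0 (degenerate controls).
    """
    if metric not in phenotypes.columns:
        raise ValueError(f"metric {metric!r} not in phenotype table")
    tab = phenotypes
    nt_tab = tab.loc[tab["is_nontargeting"]]
    if nt_tab.empty:
        raise ValueError("phenotype table has no non-targeting sgRNAs")
    nt_values = nt_tab[metric].to_numpy(dtype=float)
    nt_values = nt_values[~np.isnan(nt_values)]
    if nt_values.size == 0:
        raise ValueError("all non-targeting phenotypes are missing")

    targeting = tab.loc[~tab["is_nontargeting"]]
    groups = [
        (gene, tss,
         grp["sgrna_id"].to_numpy(dtype=object),
         grp[metric].to_numpy(dtype=float))
        for (gene, tss), grp in targeting.groupby(["gene", "tss"], sort=True)
    ]
    per_tss = _score_groups(groups, nt_values, top_k)

    nt_lookup = nt_tab.set_index("sgrna_id")[metric]
    pseudo_groups = [
        (f"pseudo_{i + 1:05d}", "na",
         np.array(members, dtype=object),
         nt_lookup.reindex(list(members)).to_numpy(dtype=float))
        for i, members in enumerate(ncg.groups)
    ]
    pseudo = _score_groups(pseudo_groups, nt_values, top_k)

    mu = float(np.nanmean(pseudo["phenotype"]))
    sigma = float(np.nanstd(pseudo["phenotype"], ddof=1))
    if not np.isfinite(sigma) or sigma == 0.0:
        raise ValueError("degenerate negative-control genes: sigma_NCG is 0")

    for frame in (per_tss, pseudo):
        frame["z"] = (frame["phenotype"] - mu) / sigma
        frame["discriminant"] = np.abs(frame["z"]) * (-np.log10(frame["p_value"]))
        frame["is_hit"] = frame["discriminant"] >= threshold
        frame["direction"] = np.select(
            [~frame["is_hit"], frame["phenotype"] < 0],
            ["none", "sensitizing"], default="protective",
        )
        frame.loc[frame["phenotype"].isna(), "direction"] = "none"

    collapsed = collapse_tss(per_tss)
    for frame in (per_tss, pseudo, collapsed):
        frame["bh_fdr"] = bh_fdr(frame["p_value"])
    return GeneScoreResult(
        per_tss[SCORE_COLUMNS], collapsed[SCORE_COLUMNS], pseudo[SCORE_COLUMNS],
        mu, sigma, threshold, metric,
    )


def collapse_tss(per_tss: pd.DataFrame) -> pd.DataFrame:
    """Collapse multi-TSS genes to the TSS with the lowest Mann-Whitney
    p-value, retaining that TSS's row verbatim.

    Ties on p are broken by larger absolute phenotype, then TSS label order.
    """
    tab = per_tss.copy()
    tab["_absphen"] = -tab["phenotype"].abs()
    tab = tab.sort_values(
        ["gene", "p_value", "_absphen", "tss"],
        kind="mergesort", na_position="last",
    )
    out = tab.groupby("gene", sort=True).head(1).drop(columns="_absphen")
    return out.reset_index(drop=True)


# -- volcano export --------------------------------------------------------


def volcano_table(result: GeneScoreResult, include_pseudo: bool = True) -> pd.DataFrame:
    """(phenotype, -log10 p) pairs for plotting, bit-identical to the score
    table, with gene labels and hit flags."""
    frames = [result.collapsed.assign(kind="gene")]
    if include_pseudo:
        frames.append(result.pseudo.assign(kind="pseudo"))
    tab = pd.concat(frames, ignore_index=True)
    return pd.DataFrame(
        {
            "gene": tab["gene"],
            "kind": tab["kind"],
            "phenotype": tab["phenotype"],
            "neglog10_p": -np.log10(tab["p_value"]),
            "discriminant": tab["discriminant"],
            "is_hit": tab["is_hit"],
            "direction": tab["direction"],
        }
    )


def plot_volcano(result: GeneScoreResult, path: str | Path,
                 highlight: list[str] | None = None) -> None:
    """Volcano plot (phenotype vs -log10 p) with the dashed discriminant
    threshold curve |z| * -log10(p) = threshold drawn on both sides."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = volcano_table(result)
    fig, ax = plt.subplots(figsize=(6, 5))
    genes = tab.loc[tab["kind"] == "gene"]
    pseudo = tab.loc[tab["kind"] == "pseudo"]
    ax.scatter(pseudo["phenotype"], pseudo["neglog10_p"], s=6, c="0.8",
               label="negative-control genes", rasterized=True)
    ax.scatter(genes["phenotype"], genes["neglog10_p"], s=8,
               c=np.where(genes["is_hit"], "tab:red", "0.4"),
               label="genes", rasterized=True)
    if highlight:
        hl = genes.loc[genes["gene"].isin(highlight)]
        ax.scatter(hl["phenotype"], hl["neglog10_p"], s=30, c="tab:green",
                   label="highlighted")
    ymax = float(np.nanmax(tab["neglog10_p"])) * 1.05 + 0.1
    for sign in (-1, 1):
        y = np.linspace(0.05, ymax, 400)
        x = result.mu_ncg + sign * result.threshold * result.sigma_ncg / y
        ax.plot(x, y, "k--", lw=1)
    span = float(np.nanmax(np.abs(genes["phenotype"]))) * 1.1 + 1e-3
    ax.set_xlim(-span, span)
    ax.set_ylim(0, ymax)
    ax.set_xlabel(f"{result.metric} phenotype (gene-level)")
    ax.set_ylabel("-log10 Mann-Whitney p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
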