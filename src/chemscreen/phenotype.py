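"""Per-sgRNA growth (gamma) and drug-sensitivity (rho) phenotypes.

gamma_i = ( e_i(untreated, t0) - median_NT e(untreated, t0) ) / D_u
rho_i   = ( e_i(treated, untreated) - median_NT e(treated, untreated) ) / dD

where e_i(A, B) = log2( f_i(A) / f_i(B) ) is the pseudocounted relative-
frequency log-ratio, median_NT is taken over the non-targeting control
sgRNAs, D_u is the untreated population's total doublings and dD the
doubling difference between treated and untreated arms. Both phenotypes are
log2 fitness effects per doubling: gamma < 0 means knockdown slows growth,
rho < 0 means knockdown sensitizes to the drug (depletion under treatment),
rho > 0 protects.

Also provides the BFP-enrichment statistic used in internally controlled
individual re-tests (flow-cytometry time courses of the sgRNA-carrying cell
fraction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountTable
from .library import SgRNALibrary

PHENOTYPE_COLUMNS = [
    "sgrna_id", "gene", "tss", "is_nontargeting",
    "e_ut_t0", "e_tr_ut", "gamma", "rho", "filtered",
]


@dataclass(frozen=True)
class PhenotypeParams:
    """Normalization parameters.

    pseudocount
        Added to every count before frequency computation; must be > 0 so all
        log-ratios are finite. Default 10.
    min_reads
        Optional filter: sgRNAs whose t0 count falls below this threshold in
        every t0 replicate are flagged and carry missing phenotypes (never 0).
        Default 0 = off.
    doublings_untreated, doubling_difference
        The physical normalizers D_u and dD. No defaults are imputed: each
        phenotype refuses to compute without its normalizer.
    """

    pseudocount: float = 10.0
    min_reads: int = 0
    doublings_untreated: float | None = None
    doubling_difference: float | None = None

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        for name in ("doublings_untreated", "doubling_difference"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class PhenotypeResult:
    """Averaged phenotype table plus per-replicate-pair values.

    ``table`` has columns ``sgrna_id, gene, tss, is_nontargeting, e_ut_t0,
    e_tr_ut, gamma, rho, filtered``; ``replicates`` keeps one column per
    replicate pairing (e.g. ``gamma[untreated_vs_t0]``) for the general
    multi-replicate case.
    """

    table: pd.DataFrame
    replicates: pd.DataFrame
    params: PhenotypeParams

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def log2_enrichment(counts_a, counts_b, pseudocount: float = 10.0) -> pd.Series:
    """log2 relative-frequency change of sample A vs sample B.

    ``e_i = log2(f_i(A) / f_i(B))`` with
    ``f_i(S) = (c_i(S) + pseudocount) / sum_j (c_j(S) + pseudocount)``.
    Invariant to uniform rescaling of either column's depth.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.asarray(counts_a, dtype=float) + pseudocount
    b = np.asarray(counts_b, dtype=float) + pseudocount
    fa = a / a.sum()
    fb = b / b.sum()
    out = np.log2(fa / fb)
    index = counts_a.index if isinstance(counts_a, pd.Series) else None
    return pd.Series(out, index=index)


def _center_on_nontargeting(e: pd.Series, nt_mask: np.ndarray) -> pd.Series:
    """Subtract the non-targeting median so that the recomputed non-targeting
    median is exactly 0.0 (iterates to absorb 1-ulp residue of even-n medians)."""
    if not nt_mask.any():
        raise ValueError("no non-targeting sgRNAs: cannot normalize phenotypes")
    out = e.copy()
    for _ in range(4):
        med = float(np.median(out[nt_mask]))
        if med == 0.0:
            break
        out = out - med
    return out


def _role_samples(counts: CountTable, role: str) -> list[str]:
    names = counts.samples_with_role(role)
    if not names:
        raise ValueError(f"count table has no sample with role {role!r}")
    return names


def _pair_phenotype(
    counts: CountTable,
    nt_mask: np.ndarray,
    role_num: str,
    role_den: str,
    divisor: float,
    pseudocount: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enrichment and normalized phenotype for every (numerator, denominator)
    replicate pairing; returns (e per pair, phenotype per pair)."""
    e_cols, p_cols = {}, {}
    for num, den in itertools.product(
        _role_samples(counts, role_num), _role_samples(counts, role_den)
    ):
        e = log2_enrichment(counts.column(num), counts.column(den), pseudocount)
        e_cols[f"{num}_vs_{den}"] = e
        p_cols[f"{num}_vs_{den}"] = _center_on_nontargeting(e, nt_mask) / divisor
    return pd.DataFrame(e_cols), pd.DataFrame(p_cols)


def compute_phenotypes(
    counts: CountTable,
    library: SgRNALibrary,
    params: PhenotypeParams,
    which: str = "both",
) -> PhenotypeResult:
    """Compute gamma and/or rho phenotypes from a count table.

    ``which`` is ``"gamma"``, ``"rho"`` or ``"both"``. With replicate samples
    of a role, phenotypes are computed per replicate pairing and averaged.
    sgRNAs failing the ``min_reads`` t0 filter are flagged and set to NaN
    (rows are removed from consideration; surviving values are never edited).
    """
    if which not in ("gamma", "rho", "both"):
        raise ValueError("which must be 'gamma', 'rho' or 'both'")
    lib = library.table.set_index("sgrna_id")
    if not counts.counts.index.equals(lib.index):
        lib = lib.reindex(counts.counts.index)
        if lib["sequence"].isna().any():
            raise ValueError("count table rows are not aligned to the library")
    nt_mask = lib["is_nontargeting"].to_numpy()

    out = pd.DataFrame(
        {
            "sgrna_id": lib.index,
            "gene": lib["gene"].to_numpy(),
            "tss": lib["tss"].to_numpy(),
            "is_nontargeting": nt_mask,
        }
    )
    rep_frames = []

    if which in ("gamma", "both"):
        if params.doublings_untreated is None:
            raise ValueError("doublings_untreated (D_u) is required for gamma")
        e, ph = _pair_phenotype(
            counts, nt_mask, "untreated", "t0",
            params.doublings_untreated, params.pseudocount,
        )
        out["e_ut_t0"] = e.mean(axis=1).to_numpy()
        out["gamma"] = ph.mean(axis=1).to_numpy()
        rep_frames.append(ph.add_prefix("gamma["). rename(columns=lambda c: c + "]"))
    else:
        out["e_ut_t0"] = np.nan
        out["gamma"] = np.nan

    if which in ("rho", "both"):
        if params.doubling_difference is None:
            raise ValueError("doubling_difference (dD) is required for rho")
        e, ph = _pair_phenotype(
            counts, nt_mask, "treated", "untreated",
            params.doubling_difference, params.pseudocount,
        )
        out["e_tr_ut"] = e.mean(axis=1).to_numpy()
        out["rho"] = ph.mean(axis=1).to_numpy()
        rep_frames.append(ph.add_prefix("rho[").rename(columns=lambda c: c + "]"))
    else:
        out["e_tr_ut"] = np.nan
        out["rho"] = np.nan

    filtered = np.zeros(len(out), dtype=bool)
    if params.min_reads > 0:
        t0_cols = counts.counts[_role_samples(counts, "t0")]
        filtered = (t0_cols.max(axis=1) < params.min_reads).to_numpy()
        out.loc[filtered, ["gamma", "rho", "e_ut_t0", "e_tr_ut"]] = np.nan
    out["filtered"] = filtered

    replicates = pd.concat(rep_frames, axis=1) if rep_frames else pd.DataFrame(index=out.index)
    replicates.insert(0, "sgrna_id", out["sgrna_id"].to_numpy())
    return PhenotypeResult(out[PHENOTYPE_COLUMNS], replicates, params)


def compute_gamma(counts: CountTable, library: SgRNALibrary,
                  params: PhenotypeParams) -> PhenotypeResult:
    """Growth phenotype only (untreated vs t0, per untreated doubling)."""
    return compute_phenotypes(counts, library, params, which="gamma")


def compute_rho(counts: CountTable, library: SgRNALibrary,
                params: PhenotypeParams) -> PhenotypeResult:
    """Sensitivity phenotype only (treated vs untreated, per doubling difference)."""
    return compute_phenotypes(counts, library, params, which="rho")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"sgrna_id": str, "gene": str, "tss": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return tab


# -- individual re-test (BFP enrichment) -----------------------------------


def retest_enrichment(bfp_fractions: pd.DataFrame) -> pd.DataFrame:
    """Enrichment of sgRNA-carrying (BFP+) cells over a treatment time course.

    ``bfp_fractions``: rows = days (index, day 0 required), columns =
    conditions; entries are BFP+ fractions in (0, 1). Returns per-condition
    ``enrichment(d) = fraction(d) / fraction(0)`` plus, when both an
    ``untreated`` and a ``treated`` column exist, their ratio
    ``relative = treated(d) / untreated(d)`` (< 1 = depleted under drug,
    i.e. the knockdown sensitizes).
    """
    if 0 not in bfp_fractions.index:
        raise ValueError("a day-0 baseline row is required")
    vals = bfp_fractions.to_numpy(dtype=float)
    if ((vals <= 0) | (vals >= 1)).any():
        raise ValueError("BFP fractions must lie strictly in (0, 1)")
    enrich = bfp_fractions / bfp_fractions.loc[0]
    if {"treated", "untreated"} <= set(bfp_fractions.columns):
        enrich = enrich.copy()
        enrich["relative"] = enrich["treated"] / enrich["untreated"]
    return enrich
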