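"""Synthetic pooled-screen generator with known ground truth.

Emulates the statistical structure a CRISPRi chemical-genetic screen analysis
assumes: a library of ~5 sgRNAs per gene plus a non-targeting set, sparse
per-gene true growth (gamma) and drug-sensitivity (rho) effects of both signs,
per-sgRNA knockdown activity in [0, 1], exponential selection over the stated
population doublings, a log-normally skewed starting representation, and
overdispersed (Dirichlet-multinomial) sequencing counts at configurable
coverage. Defaults are the screen conditions the analysis is calibrated for:
5 sgRNAs/gene, 5% sensitivity-hit genes with |rho| in [0.3, 0.6], activities
in [0.7, 1], 500 reads/sgRNA, a 6.1-doubling difference between treated and
untreated arms, and 10 untreated doublings.

The drug's pulsed dosing schedule is not modeled: the scoring model only sees
the doubling difference, so treatment is applied as a constant per-doubling
modifier.

All randomness flows from a single seed through named ``numpy`` SeedSequence
streams (library, truth, t0, one per sample), so identical seed + config give
byte-identical outputs and drawing one stream never perturbs another.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counting import CountTable, SampleInfo
from .library import NONTARGETING_GENE, NONTARGETING_TSS, SgRNALibrary

_BASES = np.array(list("ACGT"))

# stream labels -> SeedSequence spawn index
_STREAMS = {"library": 0, "truth": 1, "t0": 2, "counts_t0": 3,
            "counts_untreated": 4, "counts_treated": 5, "fastq": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


@dataclass(frozen=True)
class Dist:
    """A named scalar distribution with parameters.

    Supported kinds:

    - ``point(value)`` — degenerate point mass
    - ``normal(mu, sigma)``
    - ``uniform(lo, hi)``
    - ``beta(a, b)`` — on [0, 1]
    - ``signed_uniform(lo, hi, frac_negative)`` — magnitude ~ U(lo, hi),
      sign negative with the given probability (two-sided sparse effects)
    """

    kind: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        k, p = self.kind, self.params
        if k == "point":
            return np.full(n, p[0])
        if k == "normal":
            return rng.normal(p[0], p[1], n)
        if k == "uniform":
            return rng.uniform(p[0], p[1], n)
        if k == "beta":
            return rng.beta(p[0], p[1], n)
        if k == "signed_uniform":
            mag = rng.uniform(p[0], p[1], n)
            sign = np.where(rng.random(n) < p[2], -1.0, 1.0)
            return sign * mag
        raise ValueError(f"unknown distribution kind {k!r}")


def as_dist(obj) -> Dist:
    """Coerce a Dist, ``{"kind": ..., "params": ...}`` mapping, or
    ``(kind, params...)`` sequence into a :class:`Dist` (round-trips YAML)."""
    if isinstance(obj, Dist):
        return obj
    if isinstance(obj, dict):
        return Dist(obj["kind"], tuple(obj["params"]))
    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], str):
        return Dist(obj[0], tuple(obj[1]) if len(obj) == 2 and
                    isinstance(obj[1], (list, tuple)) else tuple(obj[1:]))
    raise TypeError(f"cannot interpret {obj!r} as a distribution")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated screen (defaults = the modeled conditions)."""

    n_genes: int = 200
    sgrnas_per_gene: int = 5
    n_tss_per_gene: int = 1
    n_nontargeting: int = 100
    frac_hit_genes: float = 0.05
    gamma_effect_dist: Dist = Dist("point", (0.0,))
    rho_effect_dist: Dist = Dist("signed_uniform", (0.3, 0.6, 0.7))
    activity_dist: Dist = Dist("uniform", (0.7, 1.0))
    doublings_untreated: float = 10.0  # D_u
    doubling_difference: float = 6.1   # delta-D between treated and untreated arms
    mean_reads_per_sgrna: float = 500.0
    dispersion: float = 0.0  # 0 => multinomial; >0 => Dirichlet-multinomial
    t0_sigma: float = 0.5    # log-normal sigma of the starting representation
    protospacer_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma_effect_dist", "rho_effect_dist", "activity_dist"):
            object.__setattr__(self, name, as_dist(getattr(self, name)))
        for name in ("n_genes", "sgrnas_per_gene", "n_tss_per_gene", "n_nontargeting"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.frac_hit_genes <= 1.0:
            raise ValueError("frac_hit_genes must lie in [0, 1]")
        for name in ("doublings_untreated", "doubling_difference", "mean_reads_per_sgrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    @property
    def n_sgrnas(self) -> int:
        return self.n_genes * self.n_tss_per_gene * self.sgrnas_per_gene + self.n_nontargeting

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth of a simulated screen.

    ``genes``: per-gene true gamma/rho (log2 fitness effect per doubling) and
    hit label; ``sgrnas``: per-sgRNA activity in [0, 1], index-aligned to the
    library. Non-targeting sgRNAs map to a gene row with gamma = rho = 0.
    """

    genes: pd.DataFrame   # gene, true_gamma, true_rho, label
    sgrnas: pd.DataFrame  # sgrna_id, gene, tss, activity, is_nontargeting

    def write(self, gene_path: str | Path, sgrna_path: str | Path) -> None:
        self.genes.to_csv(gene_path, sep="\t", index=False)
        self.sgrnas.to_csv(sgrna_path, sep="\t", index=False)


def simulate_library(config: SimConfig) -> SgRNALibrary:
    """Generate a library of unique fixed-length protospacers.

    ``n_genes * n_tss_per_gene`` targeted groups of ``sgrnas_per_gene``
    members each, plus ``n_nontargeting`` non-targeting entries. Raises if the
    protospacer length cannot host the requested number of unique sequences.
    """
    n = config.n_sgrnas
    if 4 ** config.protospacer_length < 2 * n:
        raise ValueError(
            f"sequence space exhausted: cannot draw {n} unique protospacers "
            f"of length {config.protospacer_length}"
        )
    rng = _rng(config.seed, "library")
    seqs: set[str] = set()
    while len(seqs) < n:
        draw = rng.integers(0, 4, size=(n - len(seqs), config.protospacer_length))
        seqs.update("".join(row) for row in _BASES[draw])
    seq_list = sorted(seqs)
    rng.shuffle(seq_list)

    width = len(str(config.n_genes))
    rows = []
    i = 0
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:0{width}d}"
        for t in range(config.n_tss_per_gene):
            tss = f"P{t + 1}"
            for k in range(config.sgrnas_per_gene):
                rows.append(
                    {
                        "sgrna_id": f"{gene}_{tss}_sg{k + 1}",
                        "sequence": seq_list[i],
                        "gene": gene,
                        "tss": tss,
                        "is_nontargeting": False,
                    }
                )
                i += 1
    ntw = len(str(config.n_nontargeting))
    for k in range(config.n_nontargeting):
        rows.append(
            {
                "sgrna_id": f"NTC_sg{k + 1:0{ntw}d}",
                "sequence": seq_list[i],
                "gene": NONTARGETING_GENE,
                "tss": NONTARGETING_TSS,
                "is_nontargeting": True,
            }
        )
        i += 1
    return SgRNALibrary.from_frame(pd.DataFrame(rows))


def _draw_truth(library: SgRNALibrary, config: SimConfig) -> SimTruth:
    rng = _rng(config.seed, "truth")
    tab = library.table.sort_values("sgrna_id", kind="mergesort")
    genes = sorted(tab.loc[~tab["is_nontargeting"], "gene"].unique())

    is_hit = rng.random(len(genes)) < config.frac_hit_genes
    gamma = np.where(is_hit, config.gamma_effect_dist.sample(rng, len(genes)), 0.0)
    rho = np.where(is_hit, config.rho_effect_dist.sample(rng, len(genes)), 0.0)
    label = np.full(len(genes), "none", dtype=object)
    label[(rho < 0)] = "rho-sensitizing"
    label[(rho > 0)] = "rho-protective"
    label[(rho == 0) & (gamma != 0)] = "gamma-hit"
    gene_truth = pd.DataFrame(
        {"gene": genes, "true_gamma": gamma, "true_rho": rho, "label": label}
    )
    gene_truth = pd.concat(
        [
            gene_truth,
            pd.DataFrame(
                {"gene": [NONTARGETING_GENE], "true_gamma": [0.0],
                 "true_rho": [0.0], "label": ["none"]}
            ),
        ],
        ignore_index=True,
    )

    activity = config.activity_dist.sample(rng, len(tab)).clip(0.0, 1.0)
    sg_truth = pd.DataFrame(
        {
            "sgrna_id": tab["sgrna_id"].to_numpy(),
            "gene": tab["gene"].to_numpy(),
            "tss": tab["tss"].to_numpy(),
            "activity": activity,
            "is_nontargeting": tab["is_nontargeting"].to_numpy(),
        }
    )
    return SimTruth(gene_truth, sg_truth)


def _sample_counts(rng: np.random.Generator, freqs: np.ndarray, depth: int,
                   dispersion: float) -> np.ndarray:
    if dispersion > 0:
        freqs = rng.dirichlet(freqs / dispersion)
    return rng.multinomial(depth, freqs)


def simulate_screen(
    library: SgRNALibrary, config: SimConfig
) -> tuple[CountTable, SimTruth]:
    """Simulate t0 / untreated / treated count columns plus the ground truth.

    Expected log2 enrichment of sgRNA *i* targeting gene *g* with activity
    ``a_i`` is ``D_u * a_i * gamma_g`` (untreated vs t0) and
    ``dD * a_i * rho_g`` (treated vs untreated), up to the overall
    renormalization that the non-targeting-median subtraction removes
    downstream. Counts are multinomial at the configured depth, or
    Dirichlet-multinomial when ``dispersion > 0``.
    """
    if len(library) != config.n_sgrnas:
        raise ValueError("library inconsistent with config (sgRNA count mismatch)")
    truth = _draw_truth(library, config)

    sg = truth.sgrnas
    gene_effects = truth.genes.set_index("gene")
    gamma = gene_effects.loc[sg["gene"], "true_gamma"].to_numpy()
    rho = gene_effects.loc[sg["gene"], "true_rho"].to_numpy()
    a = sg["activity"].to_numpy().copy()
    a[sg["is_nontargeting"].to_numpy()] = 0.0  # no target, no selection

    rng_t0 = _rng(config.seed, "t0")
    f0 = np.exp(rng_t0.normal(0.0, config.t0_sigma, len(sg)))
    f0 /= f0.sum()
    f_unt = f0 * np.exp2(config.doublings_untreated * a * gamma)
    f_unt /= f_unt.sum()
    f_tr = f_unt * np.exp2(config.doubling_difference * a * rho)
    f_tr /= f_tr.sum()

    depth = int(round(config.mean_reads_per_sgrna * len(sg)))
    cols = {}
    for name, freqs in (("t0", f0), ("untreated", f_unt), ("treated", f_tr)):
        rng = _rng(config.seed, f"counts_{name}")
        cols[name] = _sample_counts(rng, freqs, depth, config.dispersion)

    counts = pd.DataFrame(cols, index=pd.Index(sg["sgrna_id"], name="sgrna_id"))
    counts = counts.reindex(library.sgrna_ids).astype(np.int64)
    samples = {
        "t0": SampleInfo("t0", "t0", 0.0),
        "untreated": SampleInfo("untreated", "untreated", config.doublings_untreated),
        "treated": SampleInfo(
            "treated", "treated",
            config.doublings_untreated - config.doubling_difference
        ),
    }
    table = CountTable(counts, samples, {n: 0 for n in samples}, {n: 0 for n in samples})
    return table, truth


# -- FASTQ emission --------------------------------------------------------

# Constant vector-derived flanks surrounding the protospacer in each read.
_SCAFFOLD_5P = "TTGTGGAAAGGACGAAACACCG"
_SCAFFOLD_3P = "GTTTAAGAGCTAAGCTGGAAACAGCATAGCAAGTTTAAATAAGGC"


@dataclass(frozen=True)
class ReadLayout:
    """Geometry of emitted reads: protospacer placed at ``offset`` within a
    constant scaffold, padded/truncated to ``read_length``."""

    offset: int = 0
    read_length: int = 50
    error_rate: float = 0.0  # per-base substitution probability

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.offset < 0 or self.read_length <= 0:
            raise ValueError("offset/read_length must be non-negative/positive")


def emit_fastq(
    counts: CountTable,
    library: SgRNALibrary,
    out_dir: str | Path,
    layout: ReadLayout = ReadLayout(),
    samples: Sequence[str] | None = None,
    seed: int = 0,
    gz: bool = False,
) -> dict[str, Path]:
    """Write one FASTQ per sample; each sgRNA contributes exactly its count of
    reads carrying its protospacer at ``layout.offset``.

    With ``error_rate > 0`` each base is independently substituted with a
    uniformly chosen different base. Quality scores are a uniform placeholder.
    Returns sample name -> written path.
    """
    L = library.protospacer_length
    if layout.read_length < layout.offset + L:
        raise ValueError(
            f"read_length {layout.read_length} < offset {layout.offset} + "
            f"protospacer length {L}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = (_SCAFFOLD_5P * (layout.offset // len(_SCAFFOLD_5P) + 1))[-layout.offset:] \
        if layout.offset else ""
    tail_len = layout.read_length - layout.offset - L
    suffix = (_SCAFFOLD_3P * (tail_len // len(_SCAFFOLD_3P) + 1))[:tail_len]
    qual = "I" * layout.read_length

    rng = _rng(seed, "fastq")
    paths: dict[str, Path] = {}
    for name in (samples if samples is not None else list(counts.samples)):
        path = out_dir / (f"{name}.fastq.gz" if gz else f"{name}.fastq")
        opener = gzip.open if gz else open
        with opener(path, "wt") as fh:
            r = 0
            for sgrna_id, seq in zip(library.table["sgrna_id"], library.table["sequence"]):
                n = int(counts.counts.at[sgrna_id, name])
                for _ in range(n):
                    read = prefix + seq + suffix
                    if layout.error_rate > 0:
                        read = _corrupt(read, layout.error_rate, rng)
                    r += 1
                    fh.write(f"@{name}:{sgrna_id}:{r}\n{read}\n+\n{qual}\n")
        paths[name] = path
    return paths


def _corrupt(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit) == 0:
        return read
    for i in hit:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()
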