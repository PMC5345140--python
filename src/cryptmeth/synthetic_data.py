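"""Synthetic inputs with known ground truth for every pipeline stage.

The generator mirrors the study design it emulates: a RefSeq promoter tiling
array of 22,327 promoter regions (−1300..+500 bp of the TSS) covered by
180,000 probes, hybridized for 3 control (db/+, samples C1–C3) and 3 case
(db/db, D1–D3) mice; bisulfite amplicons sequenced as 10 clones per group;
ChIP peaks planted at chosen signed TSS offsets; qPCR Ct tables and
dual-luciferase wells drawn from specified true fold changes.

Array model: each probe's log2(MeDIP/Input) is its planted mean plus i.i.d.
Gaussian noise per replicate.  Planted methylated regions carry a base
enrichment in BOTH groups; differential regions add ``effect_size`` to one
group on top of it.  A fraction of probes receives multiplicatively inflated
replicate noise so that the CV-based quality criterion of the peak filter is
exercised.  Everything is driven by a single seeded generator, so fixtures
are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bisulfite import METHYLATED, UNDETERMINED, UNMETHYLATED, BisulfiteCloneMatrix
from .cpg_classifier import _window_stats
from .io_formats import ChIPPeak, GeneModel, ProbeTable

__all__ = [
    "ArraySimSpec",
    "TruthTable",
    "simulate_array",
    "evaluate_dmep_recovery",
    "simulate_promoter_sequences",
    "simulate_bisulfite",
    "simulate_chip_peaks",
    "simulate_qpcr",
    "simulate_luciferase",
]

_N_CHROMS = 9  # single-digit names keep lexicographic and numeric order identical
_PROMOTER_SPACING = 10_000  # bp between consecutive TSSs on a chromosome
_PROBE_LEN = 50  # bp


@dataclass(frozen=True)
class ArraySimSpec:
    """Dimensions and planted-signal parameters of a simulated promoter array.

    Defaults reproduce the emulated study: 22,327 promoters tiled by 180,000
    probes over −1300..+500 of the TSS, 3 replicates per group, ~5.4% of
    promoters carrying a differential peak and a further ~8.6% an
    enriched-but-equal peak (so ~14.1% of promoters are methylated overall).
    """

    n_promoters: int = 22_327
    n_probes_total: int = 180_000
    promoter_window: tuple[int, int] = (-1300, 500)
    replicates_per_group: int = 3
    dmep_fraction: float = 1216 / 22_327
    methylated_fraction: float = (3146 - 1216) / 22_327  # enriched, not differential
    effect_size: float = 0.6
    probe_noise_sd: float = 0.2
    cv_inflation_fraction: float = 0.1
    cv_inflation_factor: float = 5.0
    peak_base_enrichment: float = 0.5
    baseline_log2: float = 0.0
    planted_peak_probes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters <= 0 or self.n_probes_total <= 0 or self.replicates_per_group <= 0:
            raise ValueError("all counts must be positive")
        if self.n_probes_total < self.n_promoters:
            raise ValueError("spec implies <1 probe per promoter")
        for name in ("dmep_fraction", "methylated_fraction", "cv_inflation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dmep_fraction + self.methylated_fraction > 1.0:
            raise ValueError("dmep_fraction + methylated_fraction must not exceed 1")
        if self.promoter_window[0] >= self.promoter_window[1]:
            raise ValueError("promoter_window must be a non-empty interval")


@dataclass
class TruthTable:
    """Ground truth of planted peaks: one row per planted run.

    Columns: promoter_id, chrom, start, end (genomic span of the run),
    probe_lo, probe_hi (global row slice into the probe table), true_class
    ('control_higher' / 'case_higher' for differential runs, 'none' for
    enriched-but-equal runs).
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["promoter_id", "chrom", "start", "end", "probe_lo", "probe_hi", "true_class"]
        )
    )

    @property
    def differential(self) -> pd.DataFrame:
        return self.frame[self.frame["true_class"] != "none"]


def simulate_array(spec: ArraySimSpec) -> tuple[ProbeTable, TruthTable]:
    """Simulate a two-group promoter tiling array with planted peaks."""
    rng = np.random.default_rng(spec.seed)
    n_prom, n_probes = spec.n_promoters, spec.n_probes_total
    base_k = n_probes // n_prom
    remainder = n_probes % n_prom
    probes_per_prom = np.full(n_prom, base_k, dtype=int)
    probes_per_prom[:remainder] += 1

    window_lo, window_hi = spec.promoter_window
    window_len = window_hi - window_lo

    per_chrom = math.ceil(n_prom / _N_CHROMS)
    prom_idx = np.arange(n_prom)
    chrom_idx = prom_idx // per_chrom
    tss = 50_000 + (prom_idx % per_chrom) * max(_PROMOTER_SPACING, window_len + 1000)

    # even tiling: k equal bins per window, probe at each bin start
    row_prom = np.repeat(prom_idx, probes_per_prom)
    offsets = np.concatenate([np.arange(k) for k in probes_per_prom])
    bin_width = window_len / np.repeat(probes_per_prom, probes_per_prom)
    probe_len = np.minimum(_PROBE_LEN, np.floor(bin_width)).astype(int)
    start = (
        np.repeat(tss, probes_per_prom)
        + window_lo
        + np.floor(offsets * bin_width).astype(int)
    )
    end = start + np.maximum(probe_len, 1)

    mean = np.full(n_probes, float(spec.baseline_log2))
    shift_case = np.zeros(n_probes)
    shift_control = np.zeros(n_probes)

    n_dmep = int(round(spec.dmep_fraction * n_prom))
    n_equal = int(round(spec.methylated_fraction * n_prom))
    planted_proms = rng.choice(n_prom, size=n_dmep + n_equal, replace=False)
    dmep_proms, equal_proms = planted_proms[:n_dmep], planted_proms[n_dmep:]

    prom_first_row = np.concatenate(([0], np.cumsum(probes_per_prom)[:-1]))
    truth_rows = []

    def plant(prom: int, true_class: str) -> None:
        k = probes_per_prom[prom]
        run = min(spec.planted_peak_probes, k)
        lo_off = int(rng.integers(0, k - run + 1))
        lo = prom_first_row[prom] + lo_off
        hi = lo + run
        mean[lo:hi] += spec.peak_base_enrichment
        if true_class == "case_higher":
            shift_case[lo:hi] += spec.effect_size
        elif true_class == "control_higher":
            shift_control[lo:hi] += spec.effect_size
        truth_rows.append(
            {
                "promoter_id": f"prom{prom + 1:05d}",
                "chrom": f"chr{chrom_idx[prom] + 1}",
                "start": int(start[lo]),
                "end": int(end[hi - 1]),
                "probe_lo": int(lo),
                "probe_hi": int(hi),
                "true_class": true_class,
            }
        )

    directions = rng.random(n_dmep) < 0.5
    for prom, up in zip(dmep_proms, directions):
        plant(int(prom), "case_higher" if up else "control_higher")
    for prom in equal_proms:
        plant(int(prom), "none")

    inflated = rng.random(n_probes) < spec.cv_inflation_fraction
    sd = np.where(inflated, spec.probe_noise_sd * spec.cv_inflation_factor, spec.probe_noise_sd)

    r = spec.replicates_per_group
    control_names = [f"C{i + 1}" for i in range(r)]
    case_names = [f"D{i + 1}" for i in range(r)]
    noise = rng.normal(size=(n_probes, 2 * r)) * sd[:, None]
    control_vals = (mean + shift_control)[:, None] + noise[:, :r]
    case_vals = (mean + shift_case)[:, None] + noise[:, r:]

    frame = pd.DataFrame(
        {
            "probe_id": [f"P{i + 1:06d}" for i in range(n_probes)],
            "promoter_id": [f"prom{p + 1:05d}" for p in row_prom],
            "chrom": [f"chr{c + 1}" for c in chrom_idx[row_prom]],
            "start": start,
            "end": end,
        }
    )
    for j, name in enumerate(control_names):
        frame[name] = control_vals[:, j]
    for j, name in enumerate(case_names):
        frame[name] = case_vals[:, j]

    table = ProbeTable(frame, {"control": control_names, "case": case_names})
    truth = TruthTable(
        pd.DataFrame(
            truth_rows,
            columns=["promoter_id", "chrom", "start", "end", "probe_lo", "probe_hi", "true_class"],
        )
    )
    return table, truth


def evaluate_dmep_recovery(called, truth: TruthTable) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of called DMEPs vs the truth.

    A planted differential run is recovered when a called peak of the same
    promoter and class overlaps its genomic span; a called DMEP matching no
    planted differential run is a false discovery.
    """
    true_by_prom: dict[str, list[tuple[int, int, str]]] = {}
    for row in truth.differential.itertuples():
        true_by_prom.setdefault(row.promoter_id, []).append(
            (row.start, row.end, row.true_class)
        )
    recovered: set[tuple[str, int, int]] = set()
    n_false = 0
    n_called = 0
    for peak in called:
        if peak.dmep_class == "none":
            continue
        n_called += 1
        _, p_start, p_end = peak.span
        hit = False
        for t_start, t_end, t_class in true_by_prom.get(peak.promoter_id, ()):
            if p_start < t_end and t_start < p_end and t_class == peak.dmep_class:
                recovered.add((peak.promoter_id, t_start, t_end))
                hit = True
        if not hit:
            n_false += 1
    n_true = len(truth.differential)
    return {
        "sensitivity": len(recovered) / n_true if n_true else float("nan"),
        "fdp": n_false / n_called if n_called else 0.0,
        "n_true": float(n_true),
        "n_called": float(n_called),
    }


# ---------------------------------------------------------------------------
# Promoter sequences
# ---------------------------------------------------------------------------

_CORE = (600, 1100)  # indices of the planted 500-bp core; inside −700..+200 of TSS


def _draw_seq(rng: np.random.Generator, length: int, p_c: float, p_g: float,
              suppress_cpg: bool) -> np.ndarray:
    p_at = (1.0 - p_c - p_g) / 2.0
    arr = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[p_at, p_c, p_g, p_at]
    )
    if suppress_cpg:
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        arr[cg + 1] = ord("A")
    return arr


def simulate_promoter_sequences(
    n_per_class: tuple[int, int, int],
    seed: int = 0,
    length: int = 1800,
    tss_offset: int = 1300,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate promoter sequences of controlled CpG density per class.

    ``n_per_class`` is (n_HCP, n_ICP, n_LCP).  HCP sequences carry a
    CpG-rich, GC-rich 500-bp core inside −700..+200 of the TSS (GC ≥ 0.57,
    O/E ≥ 0.7 by construction, rejection-sampled for margin); ICP sequences
    carry a CpG-rich core but stay below GC 0.54 everywhere; LCP sequences
    contain no CpG dinucleotide at all.  Returns (sequences, labels).
    """
    n_hcp, n_icp, n_lcp = n_per_class
    if min(n_hcp, n_icp, n_lcp) < 0:
        raise ValueError("class counts must be non-negative")
    rng = np.random.default_rng(seed)
    core_lo, core_hi = _CORE
    if length < core_hi or tss_offset != 1300:
        core_lo = max(0, min(length - 500, tss_offset - 700))
        core_hi = core_lo + 500

    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}

    def finish(label: str, index: int, arr: np.ndarray) -> None:
        name = f"{label.lower()}_{index + 1:03d}"
        seqs[name] = arr.tobytes().decode("ascii")
        labels[name] = label

    for i in range(n_hcp):
        for _attempt in range(1000):
            arr = _draw_seq(rng, length, 0.20, 0.20, suppress_cpg=True)
            core = _draw_seq(rng, core_hi - core_lo, 0.33, 0.33, suppress_cpg=False)
            arr[core_lo:core_hi] = core
            _, gc_core, oe_core = _window_stats(
                arr[core_lo:core_hi].tobytes().decode("ascii"), core_hi - core_lo, 1
            )
            if gc_core[0] >= 0.57 and oe_core[0] >= 0.70:
                break
        else:
            raise RuntimeError("failed to construct an HCP core with margin")
        finish("HCP", i, arr)

    for i in range(n_icp):
        for _attempt in range(1000):
            arr = _draw_seq(rng, length, 0.22, 0.22, suppress_cpg=True)
            core = _draw_seq(rng, core_hi - core_lo, 0.22, 0.22, suppress_cpg=False)
            arr[core_lo:core_hi] = core
            seq = arr.tobytes().decode("ascii")
            _, gc_all, oe_all = _window_stats(seq, min(500, length), 1)
            _, gc_core, oe_core = _window_stats(
                arr[core_lo:core_hi].tobytes().decode("ascii"), core_hi - core_lo, 1
            )
            if gc_all.max() <= 0.535 and oe_core[0] >= 0.60:
                break
        else:
            raise RuntimeError("failed to construct an ICP sequence with margin")
        finish("ICP", i, arr)

    for i in range(n_lcp):
        arr = _draw_seq(rng, length, 0.20, 0.20, suppress_cpg=True)
        finish("LCP", i, arr)

    return seqs, labels


# ---------------------------------------------------------------------------
# Bisulfite clone matrices
# ---------------------------------------------------------------------------


def simulate_bisulfite(
    n_clones: int = 10,
    n_sites: int = 16,
    p_meth: tuple[float, float] = (0.685, 0.508),
    p_undetermined: float = 0.05,
    seed: int = 0,
    region_ids: tuple[str, str] = ("control", "case"),
    site_positions: Sequence[int] | None = None,
) -> tuple[BisulfiteCloneMatrix, BisulfiteCloneMatrix]:
    """Two groups' clone matrices with group-specific methylation probabilities.

    Calls are i.i.d. Bernoulli(p_meth[group]) masked to undetermined with
    probability ``p_undetermined``.  Default probabilities reproduce the
    emulated crypt comparison (68.5% vs 50.8% methylated CpGs).
    """
    if n_clones < 1 or n_sites < 1:
        raise ValueError("need at least one clone and one site")
    if not 0.0 <= p_undetermined < 1.0:
        raise ValueError("p_undetermined must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if site_positions is None:
        # 246-bp amplicon upstream of the TSS, evenly spaced CpGs
        site_positions = [-305 + round(i * 246 / max(n_sites - 1, 1)) for i in range(n_sites)]

    def one(region_id: str, p: float) -> BisulfiteCloneMatrix:
        calls = np.where(
            rng.random((n_clones, n_sites)) < p, METHYLATED, UNMETHYLATED
        ).astype(np.int8)
        mask = rng.random((n_clones, n_sites)) < p_undetermined
        # keep at least one determined call per clone
        for row in range(n_clones):
            while mask[row].all():
                mask[row] = rng.random(n_sites) < p_undetermined
        calls[mask] = UNDETERMINED
        return BisulfiteCloneMatrix(
            region_id=region_id,
            clone_ids=[f"{region_id}_clone{i + 1:02d}" for i in range(n_clones)],
            site_positions=list(site_positions),
            calls=calls,
        )

    return one(region_ids[0], p_meth[0]), one(region_ids[1], p_meth[1])


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------


def simulate_chip_peaks(
    gene_models: Sequence[GeneModel],
    offsets: Mapping[str, int] | Sequence[tuple[str, int]],
    seed: int = 0,
    width: int = 200,
    n_decoys: int = 0,
    decoy_chrom: str = "chrUn",
    group_label: str = "",
) -> list[ChIPPeak]:
    """One peak per requested (gene, signed TSS offset), plus optional decoys.

    The summit is placed exactly at the strand-adjusted offset from the
    gene's TSS; decoy peaks go to ``decoy_chrom`` (gene-free, hence
    intergenic).
    """
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in gene_models}
    items = offsets.items() if isinstance(offsets, Mapping) else list(offsets)
    peaks = []
    for gene_id, offset in items:
        gene = by_id[gene_id]
        summit = gene.tss + offset if gene.strand == "+" else gene.tss - offset
        half = width // 2
        peaks.append(
            ChIPPeak(
                chrom=gene.chrom,
                start=summit - half,
                end=summit + width - half,
                summit=summit,
                score=float(np.round(rng.uniform(50, 500), 1)),
                group_label=group_label,
            )
        )
    for i in range(n_decoys):
        summit = 5_000_000 + i * 100_000 + int(rng.integers(0, 50_000))
        half = width // 2
        peaks.append(
            ChIPPeak(
                chrom=decoy_chrom,
                start=summit - half,
                end=summit + width - half,
                summit=summit,
                score=float(np.round(rng.uniform(50, 500), 1)),
                group_label=group_label,
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# qPCR and luciferase fixtures
# ---------------------------------------------------------------------------


def simulate_qpcr(
    target: str,
    condition_folds: Mapping[str, float],
    reference_condition: str,
    n_replicates: int = 6,
    noise_sd: float = 0.15,
    seed: int = 0,
    reference_ct: float = 18.0,
    base_dct: float = 6.0,
) -> pd.DataFrame:
    """Ct table realizing the given true fold changes relative to the reference.

    ΔCt for a condition with true fold f is base_dct − log2(f) plus Gaussian
    noise of ``noise_sd`` cycles, so the ΔΔCt estimator recovers f exactly at
    zero noise.
    """
    if reference_condition not in condition_folds:
        condition_folds = {reference_condition: 1.0, **condition_folds}
    rng = np.random.default_rng(seed)
    rows = []
    for condition, fold in condition_folds.items():
        if fold <= 0:
            raise ValueError("true folds must be positive")
        for rep in range(n_replicates):
            ct_ref = reference_ct + rng.normal(0, noise_sd / 2)
            dct = base_dct - math.log2(fold) + rng.normal(0, noise_sd)
            rows.append(
                {
                    "sample_id": f"{condition}_{rep + 1}",
                    "condition": condition,
                    "target_gene": target,
                    "ct_target": ct_ref + dct,
                    "ct_reference": ct_ref,
                }
            )
    return pd.DataFrame(rows)


def simulate_luciferase(
    construct_folds: Mapping[str, float],
    n_replicates: int = 8,
    cv: float = 0.1,
    seed: int = 0,
    conditions: tuple[str, str] = ("SOX9+", "SOX9-"),
) -> pd.DataFrame:
    """Firefly/Renilla well readings realizing the given fold activations.

    The active condition's mean firefly/renilla ratio is ``fold`` times the
    empty vector's; multiplicative log-normal noise with coefficient of
    variation ``cv`` per well.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + cv**2))
    rows = []
    active, empty = conditions
    for construct, fold in construct_folds.items():
        if fold <= 0:
            raise ValueError("fold activations must be positive")
        for condition, level in ((active, fold), (empty, 1.0)):
            for _rep in range(n_replicates):
                renilla = 100.0 * rng.lognormal(-sigma**2 / 2, sigma)
                ratio = 10.0 * level * rng.lognormal(-sigma**2 / 2, sigma)
                rows.append(
                    {
                        "construct": construct,
                        "condition": condition,
                        "firefly": ratio * renilla,
                        "renilla": renilla,
                    }
                )
    return pd.DataFrame(rows)
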