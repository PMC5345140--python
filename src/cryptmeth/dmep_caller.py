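"""Enrichment-peak assembly and differential-methylation peak (DMEP) calling.

The input is a two-group MeDIP promoter-array probe table: per probe, the
log2(MeDIP/Input) ratio for each replicate of the control (db/+) and case
(db/db) group.  The caller

1. assembles, within each promoter, maximal runs of consecutive probes whose
   pooled mean log2 ratio exceeds ``probe_call_threshold`` (peak assembly);
2. scores each peak with M' = mean log2 ratio over case probes x replicates
   minus the same mean for the control group;
3. filters peaks by two criteria:
   (i)  enrichment — at least one group has a median (log2 MeDIP/Input)
        >= ``median_min`` over the peak's probes and M' is non-zero (by
        default applied symmetrically in both directions, the class given by
        the sign of M'; ``one_sided=True`` keeps only M' > 0);
   (ii) reproducibility — in BOTH groups, at least
        ``cv_pass_fraction_min`` of the peak's probes have a replicate
        coefficient of variability (sd / |mean|) <= ``cv_max``.

Peaks passing both criteria are DMEPs, classed ``case_higher`` (M' > 0) or
``control_higher`` (M' < 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ProbeTable

__all__ = [
    "DmepParams",
    "EnrichmentPeak",
    "DmepSummary",
    "assemble_peaks",
    "m_prime",
    "probe_cv",
    "call_dmeps",
    "summarize_dmeps",
]


@dataclass(frozen=True)
class DmepParams:
    """Thresholds of the differential peak filter.

    median_min / cv_max / cv_pass_fraction_min are the filter criteria; the
    remaining knobs control peak assembly, which upstream vendor software
    performed for the original arrays and is therefore fully configurable.
    """

    median_min: float = 0.3
    cv_max: float = 0.8
    cv_pass_fraction_min: float = 0.5
    min_probes_per_peak: int = 2
    probe_call_threshold: float = 0.2
    one_sided: bool = False  # keep only M' > 0 (the literal printed criterion)
    cv_scale: str = "log2"  # or "linear": CV computed on 2**ratio
    median_over: str = "probe_group_means"  # or "all_values"

    def __post_init__(self) -> None:
        if self.min_probes_per_peak < 1:
            raise ValueError("min_probes_per_peak must be >= 1")
        for name in ("median_min", "cv_max", "cv_pass_fraction_min", "probe_call_threshold"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.cv_scale not in ("log2", "linear"):
            raise ValueError("cv_scale must be 'log2' or 'linear'")
        if self.median_over not in ("probe_group_means", "all_values"):
            raise ValueError("median_over must be 'probe_group_means' or 'all_values'")


@dataclass
class EnrichmentPeak:
    """A run of consecutive probes within one promoter, with its filter state."""

    promoter_id: str
    probe_ids: list[str]
    span: tuple[str, int, int]  # (chrom, start, end), 0-based half-open
    group_median: dict[str, float] = field(default_factory=dict)
    m_prime: float = float("nan")
    cv_pass_fraction: dict[str, float] = field(default_factory=dict)
    enrichment_pass: bool = False
    cv_pass: bool = False
    dmep_class: str = "none"  # control_higher | case_higher | none
    # private: row slice into the source table (rows are promoter-contiguous)
    _rows: tuple[int, int] | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _pooled_means(table: ProbeTable) -> np.ndarray:
    return table.values().mean(axis=1)


def assemble_peaks(table: ProbeTable, params: DmepParams = DmepParams()) -> list[EnrichmentPeak]:
    """Maximal runs of enriched consecutive probes, never crossing promoters.

    A probe is enriched when its pooled mean (over all samples of both
    groups) exceeds ``params.probe_call_threshold``; runs shorter than
    ``params.min_probes_per_peak`` are discarded.
    """
    n = table.n_probes
    if n == 0:
        return []
    above = _pooled_means(table) > params.probe_call_threshold
    promoter = table.frame["promoter_id"].to_numpy()
    # run boundaries: state change of `above` or promoter change
    new_run = np.empty(n, dtype=bool)
    new_run[0] = True
    new_run[1:] = (above[1:] != above[:-1]) | (promoter[1:] != promoter[:-1])
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], n)

    probe_ids = table.frame["probe_id"].to_numpy()
    chroms = table.frame["chrom"].to_numpy()
    coord_start = table.frame["start"].to_numpy()
    coord_end = table.frame["end"].to_numpy()

    peaks = []
    for i0, i1 in zip(starts, ends):
        if not above[i0] or (i1 - i0) < params.min_probes_per_peak:
            continue
        peaks.append(
            EnrichmentPeak(
                promoter_id=str(promoter[i0]),
                probe_ids=[str(p) for p in probe_ids[i0:i1]],
                span=(str(chroms[i0]), int(coord_start[i0]), int(coord_end[i1 - 1])),
                _rows=(int(i0), int(i1)),
            )
        )
    return peaks


def _peak_rows(peak: EnrichmentPeak, table: ProbeTable) -> np.ndarray:
    if peak._rows is not None:
        i0, i1 = peak._rows
        rows = np.arange(i0, i1)
        ids = table.frame["probe_id"].to_numpy()[rows]
        if list(ids) == peak.probe_ids:
            return rows
    index = pd.Index(table.frame["probe_id"])
    locs = index.get_indexer(peak.probe_ids)
    if (locs < 0).any():
        missing = [p for p, l in zip(peak.probe_ids, locs) if l < 0]
        raise KeyError(f"peak probes not present in table: {missing}")
    return locs


def m_prime(peak: EnrichmentPeak, table: ProbeTable) -> float:
    """M' = grand mean log2 ratio (case probes x replicates) - (control)."""
    rows = _peak_rows(peak, table)
    for g in ("control", "case"):
        if not table.groups[g]:
            raise ValueError(f"group {g!r} has no replicates")
    case = table.values(table.groups["case"])[rows]
    control = table.values(table.groups["control"])[rows]
    return float(case.mean() - control.mean())


def probe_cv(table: ProbeTable, probe_id: str, group: str, *, cv_scale: str = "log2") -> float:
    """Replicate coefficient of variability of one probe within one group.

    Sample standard deviation over the group's replicates divided by the
    absolute replicate mean; +inf when the mean is exactly 0.  With
    ``cv_scale='linear'`` the log2 ratios are first transformed to linear
    scale (2**x).
    """
    cols = table.group_columns(group)
    if len(cols) < 2:
        raise ValueError(f"group {group!r} needs >=2 replicates for a CV")
    row = table.frame.loc[table.frame["probe_id"] == probe_id, cols]
    if row.empty:
        raise KeyError(f"no probe {probe_id!r} in table")
    x = row.to_numpy(dtype=float).ravel()
    if cv_scale == "linear":
        x = 2.0 ** x
    mean = x.mean()
    sd = x.std(ddof=1)
    if mean == 0.0:
        return math.inf
    return float(sd / abs(mean))


def _cv_matrix(table: ProbeTable, group: str, cv_scale: str) -> np.ndarray:
    x = table.values(table.groups[group])
    if cv_scale == "linear":
        x = 2.0 ** x
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0.0, np.inf, sd / np.abs(mean))
    return cv


def call_dmeps(
    peaks: list[EnrichmentPeak],
    table: ProbeTable,
    params: DmepParams = DmepParams(),
) -> list[EnrichmentPeak]:
    """Apply the two-part differential filter; returns new peak objects.

    Criterion (i): at least one group's peak median >= ``median_min`` and
    M' non-zero (M' > 0 only, under ``one_sided``).  Criterion (ii): in both
    groups at least ``cv_pass_fraction_min`` of the peak's probes have
    CV <= ``cv_max``.  ``dmep_class`` is set by the sign of M' when both
    criteria pass.
    """
    if not peaks:
        return []
    group_means = {
        g: table.values(table.groups[g]).mean(axis=1) for g in ("control", "case")
    }
    cv_pass_probe = {
        g: _cv_matrix(table, g, params.cv_scale) <= params.cv_max
        for g in ("control", "case")
    }
    all_values = {g: table.values(table.groups[g]) for g in ("control", "case")}

    called = []
    for peak in peaks:
        rows = _peak_rows(peak, table)
        medians = {}
        for g in ("control", "case"):
            if params.median_over == "probe_group_means":
                medians[g] = float(np.median(group_means[g][rows]))
            else:
                medians[g] = float(np.median(all_values[g][rows]))
        mp = float(all_values["case"][rows].mean() - all_values["control"][rows].mean())
        cv_frac = {
            g: float(cv_pass_probe[g][rows].mean()) for g in ("control", "case")
        }
        direction_ok = mp > 0 if params.one_sided else mp != 0.0
        enrichment_pass = max(medians.values()) >= params.median_min and direction_ok
        cv_pass = all(cv_frac[g] >= params.cv_pass_fraction_min for g in ("control", "case"))
        if enrichment_pass and cv_pass:
            dmep_class = "case_higher" if mp > 0 else "control_higher"
        else:
            dmep_class = "none"
        called.append(
            replace(
                peak,
                group_median=medians,
                m_prime=mp,
                cv_pass_fraction=cv_frac,
                enrichment_pass=enrichment_pass,
                cv_pass=cv_pass,
                dmep_class=dmep_class,
            )
        )
    return called


@dataclass
class DmepSummary:
    """Counts and group-level enrichment comparison over called peaks."""

    n_peaks: int
    n_total_methylated: int  # promoters with >=1 peak meeting the enrichment level
    n_dmep: int
    n_control_higher: int
    n_case_higher: int
    mean_enrichment_per_group: dict[str, float]
    t_p: float  # NaN when undefined


def summarize_dmeps(
    called: list[EnrichmentPeak],
    table: ProbeTable,
    params: DmepParams = DmepParams(),
    equal_var: bool = True,
) -> DmepSummary:
    """Summary counts plus a two-sided t test on per-sample mean DMEP enrichment.

    ``n_total_methylated`` counts promoters with at least one peak whose
    maximum group median meets the enrichment level (regardless of
    direction/CV) — the "methylated promoter" count.  The t test (unpaired
    two-tailed Student's by default; Welch with ``equal_var=False``) compares,
    between groups, each sample's mean log2 ratio over all probes of
    DMEP-classified peaks (the per-sample relative enrichment strength).
    """
    n_dmep = sum(p.dmep_class != "none" for p in called)
    n_control = sum(p.dmep_class == "control_higher" for p in called)
    n_case = sum(p.dmep_class == "case_higher" for p in called)
    methylated_promoters = {
        p.promoter_id
        for p in called
        if p.group_median and max(p.group_median.values()) >= params.median_min
    }

    dmep_rows = np.concatenate(
        [np.arange(*p._rows) if p._rows else _peak_rows(p, table)
         for p in called if p.dmep_class != "none"]
    ) if n_dmep else np.empty(0, dtype=int)

    mean_enrichment: dict[str, float] = {}
    t_p = float("nan")
    if n_dmep:
        per_sample = {
            g: table.values(table.groups[g])[dmep_rows].mean(axis=0)
            for g in ("control", "case")
        }
        mean_enrichment = {g: float(v.mean()) for g, v in per_sample.items()}
        if all(len(v) >= 2 for v in per_sample.values()):
            t_p = float(
                stats.ttest_ind(
                    per_sample["control"], per_sample["case"], equal_var=equal_var
                ).pvalue
            )
    return DmepSummary(
        n_peaks=len(called),
        n_total_methylated=len(methylated_promoters),
        n_dmep=n_dmep,
        n_control_higher=n_control,
        n_case_higher=n_case,
        mean_enrichment_per_group=mean_enrichment,
        t_p=t_p,
    )
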