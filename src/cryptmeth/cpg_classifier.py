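"""CpG-density classification of promoter sequences (HCP / ICP / LCP).

Promoter regions (by convention 1800 bp spanning -1300..+500 of the TSS) are
scanned with a 500-bp sliding window:

* HCP — some 500-bp window lying fully inside -700..+200 of the TSS has a
  G+C fraction >= 0.55 and a CpG observed/expected ratio >= 0.6;
* LCP — no 500-bp window anywhere in the region reaches CpG O/E >= 0.4;
* ICP — everything in between.

CpG O/E follows the Gardiner-Garden convention:
O/E = (N_CpG * L) / (N_C * N_G), with N positions excluded from every count
and from the effective length L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PromoterCpGClass",
    "cpg_oe",
    "gc_fraction",
    "classify_promoter",
    "classify_fasta",
    "class_proportions",
    "HCP_GC_MIN",
    "HCP_OE_MIN",
    "LCP_OE_MAX",
    "HCP_REGION",
    "WINDOW",
]

HCP_GC_MIN = 0.55
HCP_OE_MIN = 0.6
LCP_OE_MAX = 0.4
HCP_REGION = (-700, 200)  # bp of TSS; HCP windows must lie fully inside
WINDOW = 500  # bp


@dataclass(frozen=True)
class PromoterCpGClass:
    """Classification verdict with the evidence windows behind it.

    ``best_hcp_window`` is ``(offset_bp_of_tss, gc_fraction, cpg_oe)`` of the
    qualifying window with the highest O/E (HCP only);
    ``max_oe_window_anywhere`` is ``(offset_bp_of_tss, cpg_oe)`` of the
    highest-O/E window in the whole region.  ``label`` is None when more than
    half the sequence is N.
    """

    promoter_id: str
    label: str | None
    best_hcp_window: tuple[int, float, float] | None
    max_oe_window_anywhere: tuple[int, float] | None


def _counts(seq: str) -> tuple[int, int, int, int]:
    """(n_C, n_G, n_CpG, effective_length) with N excluded everywhere."""
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = seq.count("CG")
    length = len(seq) - seq.count("N")
    return n_c, n_g, n_cg, length


def cpg_oe(seq: str) -> float:
    """CpG observed/expected ratio: (N_CpG * L) / (N_C * N_G); 0 when C or G absent."""
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("cpg_oe needs a sequence of length >= 2")
    n_c, n_g, n_cg, length = _counts(seq)
    if n_c == 0 or n_g == 0:
        return 0.0
    return n_cg * length / (n_c * n_g)


def gc_fraction(seq: str) -> float:
    """(C+G) / (A+C+G+T); N bases excluded. 0.0 for an all-N sequence."""
    seq = seq.upper()
    n_c, n_g, _, length = _counts(seq)
    if length == 0:
        return 0.0
    return (n_c + n_g) / length


def _window_stats(seq: str, window: int, step: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-window (start, gc, oe) over all window placements.

    Cumulative-sum trick: O(len) setup, O(1) per window.  CG dinucleotides
    straddling a window edge belong to the window containing both bases.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    cum = lambda x: np.concatenate(([0], np.cumsum(x)))
    c_c, c_g, c_n, c_cg = cum(is_c), cum(is_g), cum(is_n), cum(is_cg)

    starts = np.arange(0, len(arr) - window + 1, step)
    ends = starts + window
    n_c = c_c[ends] - c_c[starts]
    n_g = c_g[ends] - c_g[starts]
    n_n = c_n[ends] - c_n[starts]
    # a CG pair must lie fully inside the window: count starts in [s, e-1)
    n_cg = c_cg[ends - 1] - c_cg[starts]
    length = window - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(length > 0, (n_c + n_g) / np.maximum(length, 1), 0.0)
        oe = np.where((n_c > 0) & (n_g > 0), n_cg * length / np.maximum(n_c * n_g, 1), 0.0)
    return starts, gc, oe


def classify_promoter(
    seq: str,
    promoter_id: str = "",
    tss_offset: int = 1300,
    window: int = WINDOW,
    step: int = 1,
) -> PromoterCpGClass:
    """Classify one promoter sequence by sliding-window CpG density.

    ``tss_offset`` is the 0-based index of the TSS within ``seq`` (1300 for
    the standard -1300..+500 region), so that window offsets can be reported
    in bp of the TSS.  A sequence shorter than ``window`` is scored by its
    single full-length window; one with >50% N gets ``label=None`` with a
    warning.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("cannot classify an empty sequence")
    if seq.count("N") > len(seq) / 2:
        warnings.warn(f"promoter {promoter_id or '<unnamed>'}: >50% N, label withheld")
        return PromoterCpGClass(promoter_id, None, None, None)

    eff_window = min(window, len(seq))
    starts, gc, oe = _window_stats(seq, eff_window, step)

    i_max = int(np.argmax(oe))
    max_oe_window = (int(starts[i_max]) - tss_offset, float(oe[i_max]))

    # HCP candidates: windows fully inside the -700..+200 region
    lo = tss_offset + HCP_REGION[0]
    hi = tss_offset + HCP_REGION[1]
    in_region = (starts >= lo) & (starts + eff_window <= hi)
    if eff_window < window:
        in_region = np.ones_like(in_region)  # degenerate short sequence
    qualifies = in_region & (gc >= HCP_GC_MIN) & (oe >= HCP_OE_MIN)

    best_hcp = None
    if qualifies.any():
        cand = np.flatnonzero(qualifies)
        j = cand[np.argmax(oe[cand])]
        best_hcp = (int(starts[j]) - tss_offset, float(gc[j]), float(oe[j]))
        label = "HCP"
    elif float(oe[i_max]) < LCP_OE_MAX:
        label = "LCP"
    else:
        label = "ICP"
    return PromoterCpGClass(promoter_id, label, best_hcp, max_oe_window)


def classify_fasta(
    seqs: Mapping[str, str], tss_offset: int = 1300, window: int = WINDOW, step: int = 1
) -> dict[str, PromoterCpGClass]:
    return {
        name: classify_promoter(s, name, tss_offset=tss_offset, window=window, step=step)
        for name, s in seqs.items()
    }


def class_proportions(labels: Iterable[str | None]) -> dict[str, float]:
    """Percentages of HCP/ICP/LCP among classified promoters (None excluded)."""
    counted = [l for l in labels if l is not None]
    if not counted:
        return {}
    return {
        cls: 100.0 * sum(l == cls for l in counted) / len(counted)
        for cls in ("HCP", "ICP", "LCP")
    }
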