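"""Independent brute-force re-implementations used as test oracles.

These deliberately use plain Python (statistics module, substring scans)
rather than the package's vectorized code paths.
"""

import statistics


def brute_force_dmep_calls(table, params):
    """Literal probe-by-probe evaluation of peak assembly and the two filter criteria.

    Returns a list of dicts, one per peak:
    {promoter_id, probe_ids, median_control, median_case, m_prime,
     cv_frac_control, cv_frac_case, dmep_class}.
    """
    control = table.groups["control"]
    case = table.groups["case"]
    frame = table.frame
    peaks = []
    for promoter_id in dict.fromkeys(frame["promoter_id"]):
        sub = frame[frame["promoter_id"] == promoter_id]
        run: list = []
        runs: list = []
        for _, row in sub.iterrows():
            vals = [row[s] for s in control + case]
            pooled = sum(vals) / len(vals)
            if pooled > params.probe_call_threshold:
                run.append(row)
            else:
                if run:
                    runs.append(run)
                run = []
        if run:
            runs.append(run)
        for run in runs:
            if len(run) < params.min_probes_per_peak:
                continue
            medians = {}
            cv_frac = {}
            for group, cols in (("control", control), ("case", case)):
                probe_means = [sum(r[s] for s in cols) / len(cols) for r in run]
                medians[group] = statistics.median(probe_means)
                n_pass = 0
                for r in run:
                    reps = [r[s] for s in cols]
                    mean = sum(reps) / len(reps)
                    if mean == 0:
                        continue  # infinite CV never passes
                    if statistics.stdev(reps) / abs(mean) <= params.cv_max:
                        n_pass += 1
                cv_frac[group] = n_pass / len(run)
            case_vals = [r[s] for r in run for s in case]
            control_vals = [r[s] for r in run for s in control]
            mp = sum(case_vals) / len(case_vals) - sum(control_vals) / len(control_vals)
            direction_ok = mp > 0 if params.one_sided else mp != 0
            enrich = max(medians.values()) >= params.median_min and direction_ok
            cv_ok = all(cv_frac[g] >= params.cv_pass_fraction_min for g in ("control", "case"))
            if enrich and cv_ok:
                dmep_class = "case_higher" if mp > 0 else "control_higher"
            else:
                dmep_class = "none"
            peaks.append(
                {
                    "promoter_id": promoter_id,
                    "probe_ids": [r["probe_id"] for r in run],
                    "median_control": medians["control"],
                    "median_case": medians["case"],
                    "m_prime": mp,
                    "cv_frac_control": cv_frac["control"],
                    "cv_frac_case": cv_frac["case"],
                    "dmep_class": dmep_class,
                }
            )
    return peaks


def _sub_gc(sub):
    n_c, n_g = sub.count("C"), sub.count("G")
    length = len(sub) - sub.count("N")
    return (n_c + n_g) / length if length else 0.0


def _sub_oe(sub):
    n_c, n_g = sub.count("C"), sub.count("G")
    length = len(sub) - sub.count("N")
    if n_c == 0 or n_g == 0:
        return 0.0
    return sub.count("CG") * length / (n_c * n_g)


def brute_force_classify(seq, tss_offset=1300, window=500):
    """Exhaustive 500-bp substring evaluation of the CpG-density rules."""
    seq = seq.upper()
    w = min(window, len(seq))
    all_windows = [seq[s:s + w] for s in range(0, len(seq) - w + 1)]
    lo, hi = tss_offset - 700, tss_offset + 200
    hcp = False
    for s in range(0, len(seq) - w + 1):
        if w < window or (s >= lo and s + w <= hi):
            sub = seq[s:s + w]
            if _sub_gc(sub) >= 0.55 and _sub_oe(sub) >= 0.6:
                hcp = True
                break
    if hcp:
        return "HCP"
    if max(_sub_oe(sub) for sub in all_windows) < 0.4:
        return "LCP"
    return "ICP"


# qualitative perturbation outcomes of the studied Wnt-pathway genes:
# (knockdown fold, p), (overexpression fold, p)
REGULATION_PATTERNS = {
    "Wnt4": ((0.4, 0.001), (2.1, 0.004)),
    "Tab2": ((0.55, 0.01), (1.8, 0.02)),
    "Sox4": ((0.6, 0.03), (1.6, 0.04)),
    "Fzd8": ((0.3, 0.0005), (2.5, 0.001)),
    "Cdk1": ((1.9, 0.002), (0.5, 0.01)),
    "Rac1": ((1.1, 0.6), (0.95, 0.7)),
    "Ctbp1": ((1.05, 0.8), (1.02, 0.9)),
}
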