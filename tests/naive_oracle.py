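"""Independent naive recomputation of the 127-variable registry.

Deliberately shares no segmentation or statistics code with the package:
every variable is derived by rescanning the raw period list with plain
loops and the standard-library ``statistics`` module.  Used as the oracle
in equivalence tests (truncated-wave criterion disabled on both sides).
"""

import statistics

NP, C, PD, PD2, PD3, D, PPD, E1E, E1, E2, F, G = (
    "Np", "C", "pd", "pdII-2", "pdII-3", "D", "p-pd", "E1e", "E1", "E2", "F", "G")


def naive_variables(rec, se2_thr=10.0, brief_thr=3.0):
    """Return {acronym: value-or-None} for all 127 registry variables."""
    P = [(p.label, p.start, p.duration) for p in rec.periods]
    total = rec.total_duration
    out = {}

    def durs(lab):
        return [d for l, _, d in P if l == lab]

    def fam(prefix, vals, mx=False):
        out[f"n_{prefix}"] = len(vals)
        out[f"a_{prefix}"] = statistics.fmean(vals) if vals else None
        out[f"m_{prefix}"] = statistics.median(vals) if vals else None
        out[f"s_{prefix}"] = sum(vals)
        if mx:
            out[f"mx_{prefix}"] = max(vals) if vals else None

    # ---- probes: maximal runs of non-Np ---------------------------------
    probes, cur = [], []
    for tup in P:
        if tup[0] == NP:
            if cur:
                probes.append(cur)
                cur = []
        else:
            cur.append(tup)
    if cur:
        probes.append(cur)

    def pdur(pr):
        return sum(d for _, _, d in pr)

    def pstart(pr):
        return pr[0][1]

    def probe_index_of(start_time):
        for k, pr in enumerate(probes):
            if any(s == start_time for _, s, _ in pr):
                return k
        return None

    # ---- phloem phases: contiguous E1/E2 runs ---------------------------
    phases, cur = [], []
    for tup in P:
        if tup[0] in (E1, E2):
            cur.append(tup)
        else:
            if cur:
                phases.append(cur)
                cur = []
    if cur:
        phases.append(cur)

    def phase_dur(ph):
        return sum(d for _, _, d in ph)

    def reaches(ph):
        return any(l == E2 for l, _, _ in ph)

    # ---- derived period classes ----------------------------------------
    se2 = [(l, s, d) for l, s, d in P if l == E2 and d > se2_thr]
    sg_e1, fr_e1, init_e1 = [], [], []
    for ph in phases:
        labs = [l for l, _, _ in ph]
        if not reaches(ph):
            sg_e1 += [(l, s, d) for l, s, d in ph if l == E1]
            continue
        first_e1 = labs.index(E1) if E1 in labs else None
        if first_e1 is not None and E2 in labs[first_e1 + 1:]:
            init_e1.append(ph[first_e1])
        for k, (l, s, d) in enumerate(ph):
            if l == E1 and E2 in labs[:k] and E2 in labs[k + 1:]:
                fr_e1.append((l, s, d))
    e12 = [(pstart(ph), phase_dur(ph)) for ph in phases if reaches(ph)]

    # ---- potential-drop groups -----------------------------------------
    groups = []  # (kind, probe_idx, start, ii1, ii2, ii3)
    i = 0
    while i < len(P):
        l, s, d = P[i]
        if l in (PD, PPD):
            ii2 = ii3 = None
            j = i + 1
            if j < len(P) and P[j][0] == PD2:
                ii2 = P[j][2]
                j += 1
                if j < len(P) and P[j][0] == PD3:
                    ii3 = P[j][2]
                    j += 1
            groups.append((l, probe_index_of(s), s, d, ii2, ii3))
            i = j
        else:
            i += 1
    std = [g for g in groups if g[0] == PD]
    ppd = [g for g in groups if g[0] == PPD]

    def gtotal(g):
        return g[3] + (g[4] or 0.0) + (g[5] or 0.0)

    # ===== non-sequential =================================================
    fam("Np", durs(NP), mx=True)
    fam("Pr", [pdur(pr) for pr in probes])
    out["n_bPr"] = sum(1 for pr in probes if pdur(pr) < brief_thr)
    for lab in (C, F, G, E1E, D):
        fam(lab, durs(lab))
    out["n_sgD"] = sum(
        1 for i, (l, _, _) in enumerate(P)
        if l == D and (i + 1 >= len(P) or P[i + 1][0] != E1)
    )
    fam("sgE1", [d for _, _, d in sg_e1], mx=True)
    fam("frE1", [d for _, _, d in fr_e1], mx=True)
    fam("E1", durs(E1), mx=True)
    fam("E12", [d for _, d in e12], mx=True)
    fam("E2", durs(E2), mx=True)
    fam("sE2", [d for _, _, d in se2])

    # ===== durations of named single periods =============================
    np_list = durs(NP)
    out["d_2Np"] = np_list[1] if len(np_list) >= 2 else None
    out["d_1Pr"] = pdur(probes[0]) if probes else None
    out["d_1st_E"] = phase_dur(phases[0]) if phases else None
    first_e2 = next(((l, s, d) for l, s, d in P if l == E2), None)
    out["d_1st_E2"] = first_e2[2] if first_e2 else None
    out["a_1st E1_followed_E2"] = statistics.fmean([d for _, _, d in init_e1]) if init_e1 else None
    e2_per_phase = [sum(d for l, _, d in ph if l == E2) for ph in phases if reaches(ph)]
    out["a_s_E2/phloem_ph"] = statistics.fmean(e2_per_phase) if e2_per_phase else None

    # ===== sequential times ==============================================
    out["t > 1Pr"] = pstart(probes[0]) if probes else total
    first_e = next(((l, s, d) for l, s, d in P if l in (E1, E2)), None)
    first_e12 = e12[0] if e12 else None
    first_se2 = se2[0] if se2 else None

    def t_from_first_probe(onset):
        if not probes:
            return None
        if onset is None:
            return total - pstart(probes[0])
        return onset - pstart(probes[0])

    out["t > 1E"] = t_from_first_probe(first_e[1] if first_e else None)
    out["t > 1E12"] = t_from_first_probe(first_e12[0] if first_e12 else None)
    out["t > 1E2"] = t_from_first_probe(first_e2[1] if first_e2 else None)
    out["t > 1sE2"] = t_from_first_probe(first_se2[1] if first_se2 else None)

    def t_within_probe(tup):
        if tup is None:
            return None
        k = probe_index_of(tup[1])
        return None if k is None else tup[1] - pstart(probes[k])

    out["tPr > 1E/1Pr"] = t_within_probe(first_e)
    out["tPr > 1E2/1Pr"] = t_within_probe(first_e2)
    out["tPr > 1sE2/1Pr"] = t_within_probe(first_se2)

    # ===== sequential durations ==========================================
    def c_in_probe_before(probe, t):
        return sum(min(s + d, t) - s for l, s, d in probe if l == C and s < t)

    def c_before_first_e(probe):
        onset = next((s for l, s, d in probe if l in (E1, E2)), None)
        return None if onset is None else c_in_probe_before(probe, onset)

    k_e = probe_index_of(first_e[1]) if first_e else None
    out["tC > 1E/1Pr"] = c_before_first_e(probes[k_e]) if k_e is not None else None
    k_se2 = probe_index_of(first_se2[1]) if first_se2 else None
    out["tC > 1sE2/1Pr"] = (
        c_in_probe_before(probes[k_se2], first_se2[1]) if k_se2 is not None else None
    )
    c_times = [t for t in (c_before_first_e(pr) for pr in probes) if t is not None]
    out["atC > 1E/Pr"] = statistics.fmean(c_times) if c_times else None
    out["mntC > 1E/Pr"] = min(c_times) if c_times else None
    out["s_np.1E"] = (
        sum(d for l, s, d in P if l == NP and s < first_e[1]) if first_e else None
    )
    e1_before_e2 = [P[i][2] for i in range(len(P) - 1) if P[i][0] == E1 and P[i + 1][0] == E2]
    se2_starts = {s for _, s, _ in se2}
    e1_before_se2 = [P[i][2] for i in range(len(P) - 1)
                     if P[i][0] == E1 and P[i + 1][0] == E2 and P[i + 1][1] in se2_starts]
    out["d_E1followedbyE2"] = sum(e1_before_e2) if e1_before_e2 else None
    out["d_E1followedbysE2"] = sum(e1_before_se2) if e1_before_se2 else None

    # ===== sequential counts =============================================
    n_pr = len(probes)
    brief_flags = [pdur(pr) < brief_thr for pr in probes]
    out["n_Pr > 1E"] = k_e if k_e is not None else n_pr
    out["n_brPr > 1E"] = (sum(brief_flags[:k_e]) if k_e is not None else sum(brief_flags))
    k_e2 = probe_index_of(first_e2[1]) if first_e2 else None
    out["n_Pr > 1E2"] = k_e2 if k_e2 is not None else n_pr
    out["n_Pr > 1sE2"] = k_se2 if k_se2 is not None else n_pr
    if first_se2 is None:
        out["n_E2 > 1sE2"] = len(durs(E2))
    else:
        out["n_E2 > 1sE2"] = sum(1 for l, s, _ in P if l == E2 and s < first_se2[1])
    out["n_Pr.after1E"] = (n_pr - k_e - 1) if k_e is not None else None
    out["n_bPr.after1E"] = sum(brief_flags[k_e + 1:]) if k_e is not None else None
    out["n_ Pr < 1sE2"] = (n_pr - k_se2 - 1) if k_se2 is not None else None

    # ===== potential indices =============================================
    s_pr = sum(pdur(pr) for pr in probes)
    for lab in (C, F, G, E1, E2):
        out[f"%probtimein{lab}"] = 100.0 * sum(durs(lab)) / s_pr if s_pr > 0 else None
    out["E2/C_ratio"] = sum(durs(E2)) / sum(durs(C)) if sum(durs(C)) > 0 else None
    first_e1 = next(((l, s, d) for l, s, d in P if l == E1), None)
    if first_e1 is None or total - first_e1[1] <= 0:
        out["E1_index"] = None
    else:
        out["E1_index"] = 100.0 * sum(durs(E1)) / (total - first_e1[1])
    out["frE1_ratio"] = len(fr_e1) / len(durs(E1)) if durs(E1) else None
    if first_e2 is None or total - first_e2[1] <= 0:
        out["E2_index"] = None
    else:
        out["E2_index"] = 100.0 * sum(durs(E2)) / (total - first_e2[1])
    out["%_sE2"] = 100.0 * len(se2) / len(durs(E2)) if durs(E2) else None
    out["%Phloem_ph_fail"] = (
        100.0 * sum(1 for ph in phases if not reaches(ph)) / len(phases) if phases else None
    )

    # ===== potential drops ===============================================
    std_tot = [gtotal(g) for g in std]
    out["n_pd"] = len(std)
    out["a_pd"] = statistics.fmean(std_tot) if std_tot else None
    out["m_pd"] = statistics.median(std_tot) if std_tot else None
    out["s_pd"] = sum(std_tot)
    s_c = sum(durs(C))
    out["n_pd/minC"] = len(std) / s_c if s_c > 0 else None
    for name, slot in (("II-1", 3), ("II-2", 4), ("II-3", 5)):
        vals = [g[slot] for g in std if g[slot] is not None]
        out[f"a_pd {name}"] = statistics.fmean(vals) if vals else None
        out[f"m_pd {name}"] = statistics.median(vals) if vals else None
        out[f"s_pd {name}"] = sum(vals)
    out["t > 1pd"] = std[0][2] if std else total
    in_first = [g for g in std if g[1] == 0]
    out["t > 1pd/1Pr"] = (in_first[0][2] - pstart(probes[0])) if (probes and in_first) else None
    lat = []
    for k in sorted({g[1] for g in std if g[1] is not None}):
        lat.append(min(g[2] for g in std if g[1] == k) - pstart(probes[k]))
    out["at > 1pd/Pr"] = statistics.fmean(lat) if lat else None
    out["m_Pr > 1pd"] = statistics.median(lat) if lat else None
    out["mnt_1pd/1pd"] = min(lat) if lat else None
    out["n_pd/1Pr"] = len(in_first) if probes else None
    out["%_Pr_pd"] = (
        100.0 * len({g[1] for g in std if g[1] is not None}) / n_pr if n_pr else None
    )
    out["n_Pr > 1pd"] = min(g[1] for g in std) if std else n_pr
    out["s_pdII-3/5pd"] = sum(g[5] for g in std[:5] if g[5] is not None)
    ppd_tot = [gtotal(g) for g in ppd]
    out["n_p-pd"] = len(ppd)
    out["a_p-pd"] = statistics.fmean(ppd_tot) if ppd_tot else None
    out["m_p-pd"] = statistics.median(ppd_tot) if ppd_tot else None
    out["s_p-pd"] = sum(ppd_tot)
    return out
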