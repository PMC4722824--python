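"""Analysis of molecular variance on pairwise distance matrices.

Sums of squares follow Excoffier, Smouse & Quattro (1992): the distance
value supplied is used as the squared inter-individual deviation (for
sequence data this is conventionally the TN93-corrected distance, matching
the common "pairwise difference + distance model" usage).  Variance
components may be negative as estimated; the reported percentages floor
components at zero with a logged note.

Permutation schemes: F_CT permutes whole populations among groups; F_SC
permutes individuals among populations within their group; F_ST permutes
individuals among all populations.  p-values use (b+1)/(m+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..popdata import PopulationMap, SequenceAlignment
from .distances import tn93_matrix

logger = logging.getLogger(__name__)

__all__ = ["AmovaResult", "amova", "amova_from_distances"]


@dataclass
class AmovaResult:
    levels: int
    df: dict[str, int]
    ss: dict[str, float]
    components: dict[str, float]  # sigma_a (among groups), sigma_b, sigma_c
    percentages: dict[str, float]
    fixation: dict[str, float]  # F_CT, F_SC, F_ST (1-level: F_ST only)
    p_values: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0


def _ss_within(d2: np.ndarray, parts: list[np.ndarray]) -> float:
    total = 0.0
    for idx in parts:
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def _components_one_level(d2, pop_parts):
    n = d2.shape[0]
    sizes = np.array([len(p) for p in pop_parts], dtype=float)
    P = len(pop_parts)
    ss_total = d2.sum() / (2.0 * n)
    ss_wp = _ss_within(d2, pop_parts)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, n - P
    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    n_prime = (n - (sizes**2).sum() / n) / (P - 1)
    sigma_a = (ss_ap / df_ap - sigma_c) / n_prime if df_ap > 0 else 0.0
    return ss_total, ss_ap, ss_wp, df_ap, df_wp, sigma_a, sigma_c


def _components_two_level(d2, group_parts):
    """group_parts: list of (group) lists of population index arrays."""
    n = d2.shape[0]
    pop_parts = [p for g in group_parts for p in g]
    grp_idx = [np.concatenate(g) for g in group_parts]
    P = len(pop_parts)
    G = len(group_parts)
    ss_total = d2.sum() / (2.0 * n)
    ss_wp = _ss_within(d2, pop_parts)
    ss_wg = _ss_within(d2, grp_idx)
    ss_ap_wg = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    df_ag, df_ap, df_wp = G - 1, P - G, n - P

    sizes = {id(p): len(p) for p in pop_parts}
    n_g = np.array([len(g) for g in grp_idx], dtype=float)
    sum_np2_over_ng = sum(
        sum(len(p) ** 2 for p in g) / len(gi)
        for g, gi in zip(group_parts, grp_idx)
    )
    sum_np2 = sum(len(p) ** 2 for p in pop_parts)
    n1 = (n - sum_np2_over_ng) / df_ap if df_ap > 0 else 1.0
    n2 = (sum_np2_over_ng - sum_np2 / n) / df_ag
    n3 = (n - (n_g**2).sum() / n) / df_ag

    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_b = (ss_ap_wg / df_ap - sigma_c) / n1 if df_ap > 0 else 0.0
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return (ss_total, ss_ag, ss_ap_wg, ss_wp, df_ag, df_ap, df_wp,
            sigma_a, sigma_b, sigma_c)


def amova_from_distances(
    d2: np.ndarray,
    populations: list[str],
    groups: list[str] | None = None,
    n_perm: int = 0,
    rng_seed: int = 0,
) -> AmovaResult:
    """AMOVA on a precomputed (squared-)distance matrix.

    ``populations[i]`` labels individual i; ``groups[i]`` (optional) adds a
    second level.  With ``groups`` the analysis is 2-level (among groups /
    among populations within groups / within populations).
    """
    d2 = np.asarray(d2, dtype=float)
    n = d2.shape[0]
    pops = np.asarray(populations)
    uniq_pops = list(dict.fromkeys(populations))
    if len(uniq_pops) < 2:
        raise ValueError("AMOVA requires at least 2 populations")
    rng = np.random.default_rng(rng_seed)

    if groups is None:
        pop_parts = [np.flatnonzero(pops == p) for p in uniq_pops]
        ss_total, ss_ap, ss_wp, df_ap, df_wp, sigma_a, sigma_c = (
            _components_one_level(d2, pop_parts)
        )
        tot = sigma_a + sigma_c
        fst = sigma_a / tot if tot > 0 else float("nan")
        comps = {"among_populations": sigma_a, "within_populations": sigma_c}
        floored = {k: max(v, 0.0) for k, v in comps.items()}
        if any(v < 0 for v in comps.values()):
            logger.info("negative variance component floored at 0 for percentages")
        denom = sum(floored.values())
        pct = {k: 100.0 * v / denom if denom > 0 else float("nan")
               for k, v in floored.items()}
        p_values = {}
        if n_perm > 0:
            count = 0
            labels = pops.copy()
            for _ in range(n_perm):
                rng.shuffle(labels)
                parts = [np.flatnonzero(labels == p) for p in uniq_pops]
                *_, sa, sc = _components_one_level(d2, parts)
                f = sa / (sa + sc) if (sa + sc) > 0 else -np.inf
                if f >= fst:
                    count += 1
            p_values["F_ST"] = (count + 1) / (n_perm + 1)
        return AmovaResult(
            levels=1,
            df={"among_populations": df_ap, "within_populations": df_wp,
                "total": n - 1},
            ss={"among_populations": ss_ap, "within_populations": ss_wp,
                "total": ss_total},
            components=comps,
            percentages=pct,
            fixation={"F_ST": fst},
            p_values=p_values,
            n_perm=n_perm,
        )

    grps = np.asarray(groups)
    uniq_grps = list(dict.fromkeys(groups))
    if len(uniq_grps) < 2:
        raise ValueError("2-level AMOVA requires at least 2 groups")
    pop_to_group = {}
    for p, g in zip(populations, groups):
        if pop_to_group.setdefault(p, g) != g:
            raise ValueError(f"population {p!r} spans two groups")

    def build_parts(pop_labels, p2g):
        by_group: dict[str, list[np.ndarray]] = {g: [] for g in uniq_grps}
        for p in dict.fromkeys(pop_labels):
            idx = np.flatnonzero(np.asarray(pop_labels) == p)
            by_group[p2g[p]].append(idx)
        return [by_group[g] for g in uniq_grps if by_group[g]]

    parts = build_parts(populations, pop_to_group)
    (ss_total, ss_ag, ss_ap, ss_wp, df_ag, df_ap, df_wp,
     sigma_a, sigma_b, sigma_c) = _components_two_level(d2, parts)

    tot = sigma_a + sigma_b + sigma_c
    f_ct = sigma_a / tot if tot > 0 else float("nan")
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else float("nan")
    f_st = (sigma_a + sigma_b) / tot if tot > 0 else float("nan")
    comps = {"among_groups": sigma_a, "among_populations_within_groups": sigma_b,
             "within_populations": sigma_c}
    floored = {k: max(v, 0.0) for k, v in comps.items()}
    if any(v < 0 for v in comps.values()):
        logger.info("negative variance component floored at 0 for percentages")
    denom = sum(floored.values())
    pct = {k: 100.0 * v / denom if denom > 0 else float("nan")
           for k, v in floored.items()}

    p_values = {}
    if n_perm > 0:
        # F_CT: permute populations among groups (keep population composition)
        count_ct = 0
        pop_list = list(dict.fromkeys(populations))
        grp_of = [pop_to_group[p] for p in pop_list]
        for _ in range(n_perm):
            perm = rng.permutation(len(pop_list))
            p2g = {pop_list[i]: grp_of[perm[i]] for i in range(len(pop_list))}
            try:
                pts = build_parts(populations, p2g)
                if len(pts) < 2:
                    continue
                *_, sa, sb, sc = _components_two_level(d2, pts)
            except Exception:  # pragma: no cover
                continue
            t = sa + sb + sc
            f = sa / t if t > 0 else -np.inf
            if f >= f_ct:
                count_ct += 1
        p_values["F_CT"] = (count_ct + 1) / (n_perm + 1)

        # F_SC: permute individuals among populations within groups
        count_sc = 0
        for _ in range(n_perm):
            labels = pops.copy()
            for g in uniq_grps:
                gi = np.flatnonzero(grps == g)
                labels[gi] = labels[gi[rng.permutation(len(gi))]]
            pts = build_parts(labels, pop_to_group)
            *_, sa, sb, sc = _components_two_level(d2, pts)
            f = sb / (sb + sc) if (sb + sc) > 0 else -np.inf
            if f >= f_sc:
                count_sc += 1
        p_values["F_SC"] = (count_sc + 1) / (n_perm + 1)

        # F_ST: permute individuals among all populations
        count_st = 0
        for _ in range(n_perm):
            labels = pops[rng.permutation(n)]
            pts = build_parts(labels, pop_to_group)
            *_, sa, sb, sc = _components_two_level(d2, pts)
            t = sa + sb + sc
            f = (sa + sb) / t if t > 0 else -np.inf
            if f >= f_st:
                count_st += 1
        p_values["F_ST"] = (count_st + 1) / (n_perm + 1)

    return AmovaResult(
        levels=2,
        df={"among_groups": df_ag, "among_populations_within_groups": df_ap,
            "within_populations": df_wp, "total": n - 1},
        ss={"among_groups": ss_ag, "among_populations_within_groups": ss_ap,
            "within_populations": ss_wp, "total": ss_total},
        components=comps,
        percentages=pct,
        fixation={"F_CT": f_ct, "F_SC": f_sc, "F_ST": f_st},
        p_values=p_values,
        n_perm=n_perm,
    )


def amova(
    alignment: SequenceAlignment,
    popmap: PopulationMap,
    grouping: str = "1-level",
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> AmovaResult:
    """AMOVA on TN93 distances for an alignment with a population map.

    ``grouping='1-level'`` partitions among/within populations only;
    ``'2-level'`` nests populations inside their mapped groups.
    """
    d2 = tn93_matrix(alignment)
    populations = [popmap.individual_to_population[i] for i in alignment.ids]
    if grouping == "1-level":
        return amova_from_distances(d2, populations, None, n_perm, rng_seed)
    if grouping == "2-level":
        groups = [popmap.group_of(i) for i in alignment.ids]
        return amova_from_distances(d2, populations, groups, n_perm, rng_seed)
    raise ValueError("grouping must be '1-level' or '2-level'")
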