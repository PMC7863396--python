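"""Metabolite-set enrichment between two diet groups.

Ions are ranked by a per-ion Welch t statistic on log10 intensities; each
pathway's enrichment score (ES) is the classic weighted Kolmogorov-Smirnov
running sum over that ranking: walking down the list, hitting a member adds
|score|^p / sum of member |score|^p and a non-member subtracts
1/(N - N_members); ES is the extremum of the walk (signed). Significance
comes from sample-label permutation, which re-ranks the ions under each
shuffle and therefore preserves the inter-metabolite correlation structure
that flow-injection data certainly has. NES divides ES by the mean |null ES|
of the same sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .stats import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 3
DEFAULT_WEIGHT_P = 1.0


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    es: float
    nes: float
    p: float
    q: float
    n_members_used: int
    n_perm: int
    seed: int | None


def read_gmt(path) -> dict[str, dict]:
    """Parse a GMT file: name <TAB> description <TAB> member ids."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"GMT line has < 3 fields: {line[:60]!r}")
            sets[fields[0]] = {
                "description": fields[1],
                "members": list(dict.fromkeys(fields[2:])),
            }
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, body in sets.items():
            members = body["members"] if isinstance(body, dict) else list(body)
            desc = body.get("description", "") if isinstance(body, dict) else ""
            fh.write("\t".join([name, desc, *members]) + "\n")


def _welch_t_matrix(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Welch t per row (ion) between two sample blocks; vectorized."""
    n_a, n_b = x_a.shape[1], x_b.shape[1]
    m_a, m_b = x_a.mean(axis=1), x_b.mean(axis=1)
    v_a, v_b = x_a.var(axis=1, ddof=1), x_b.var(axis=1, ddof=1)
    se = np.sqrt(v_a / n_a + v_b / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m_a - m_b) / se, 0.0)
    return t


def rank_metabolites(
    matrix, cohort, group_a: str, group_b: str, stat: str = "welch_t"
) -> pd.DataFrame:
    """Per-ion scores between two groups, sorted descending.

    Welch t on log10 intensities (matching the per-metabolite test used for
    individual fold changes). Ties are broken by ion id so the ranking is
    deterministic.
    """
    if stat != "welch_t":
        raise InputError(f"unknown ranking statistic {stat!r}")
    ids_a = cohort.ids_in_group(group_a)
    ids_b = cohort.ids_in_group(group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise InputError("both groups need >= 2 members for ranking")
    log = np.log10(matrix.intensities)
    t = _welch_t_matrix(log[ids_a].to_numpy(), log[ids_b].to_numpy())
    df = pd.DataFrame({"ion_id": matrix.ion_ids, "score": t})
    return df.sort_values(
        ["score", "ion_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def _running_sum(scores: np.ndarray, member: np.ndarray, weight_p: float) -> np.ndarray:
    """Running-sum trace for one ranking (scores already in rank order)."""
    n = scores.size
    n_mem = int(member.sum())
    if n_mem == 0:
        raise InputError("no set members present in the ranking")
    if n_mem == n:
        inc = np.full(n, 1.0 / n)  # degenerate: everything is a member
        return np.cumsum(inc)
    w = np.where(member, np.abs(scores) ** weight_p, 0.0)
    denom = w.sum()
    if denom == 0.0:  # all member scores exactly 0 — fall back to equal steps
        w = member.astype(float)
        denom = float(n_mem)
    step = w / denom - (~member) / (n - n_mem)
    return np.cumsum(step)


def enrichment_score(
    ranked: pd.DataFrame | list, members, weight_p: float = DEFAULT_WEIGHT_P
) -> tuple[float, np.ndarray]:
    """(ES, running-sum trace) of a member set over a ranked list.

    ES is the running-sum value of maximal absolute deviation, keeping its
    sign; with weight_p = 0 the walk returns exactly to 0 at the end.
    """
    if isinstance(ranked, pd.DataFrame):
        ids = ranked["ion_id"].to_numpy()
        scores = ranked["score"].to_numpy(dtype=float)
    else:
        ids = np.array([i for i, _ in ranked])
        scores = np.array([s for _, s in ranked], dtype=float)
    member = np.isin(ids, list(members))
    trace = _running_sum(scores, member, weight_p)
    es = trace[np.argmax(np.abs(trace))]
    return float(es), trace


def resolve_members(matrix, members) -> list[str]:
    """Ions belonging to a set, directly or through any candidate annotation.

    An ambiguously annotated ion contributes to every pathway that any of its
    isomer candidates belongs to — ambiguity is propagated, not resolved.
    """
    wanted = set(members)
    hits = [i for i in matrix.ion_ids if i in wanted]
    for ion, cands in matrix.annotations.items():
        if ion not in hits and any(c in wanted for c, _ in cands):
            hits.append(ion)
    return hits


def pathway_permutation_test(
    matrix,
    cohort,
    sets: dict,
    group_a: str = "VGN",
    group_b: str = "OMN",
    n_perm: int = 999,
    seed: int | None = None,
    weight_p: float = DEFAULT_WEIGHT_P,
    min_size: int = DEFAULT_MIN_SIZE,
    null: str = "sample",
) -> pd.DataFrame:
    """Permutation p, NES, and BH q per pathway.

    ``null="sample"`` (default) permutes participant group labels and
    re-ranks all ions per shuffle — correct under inter-metabolite
    correlation. ``null="metabolite"`` keeps the observed ranking and draws
    random member sets of the same size (faster, anti-conservative under
    correlated blocks). p = (#{|ES*| >= |ES_obs|} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ids_a = cohort.ids_in_group(group_a)
    ids_b = cohort.ids_in_group(group_b)
    log = np.log10(matrix.intensities[ids_a + ids_b].to_numpy())
    n_a, n = len(ids_a), len(ids_a) + len(ids_b)
    n_ions = log.shape[0]

    # observed ranking: descending score, ties by matrix row order (= ion id)
    t_obs = _welch_t_matrix(log[:, :n_a], log[:, n_a:])
    order_obs = np.argsort(-t_obs, kind="stable")

    member_masks, names, sizes = [], [], []
    for name, body in sets.items():
        raw = body["members"] if isinstance(body, dict) else list(body)
        hits = resolve_members(matrix, raw)
        if len(hits) < min_size:
            logger.warning(
                "pathway %s skipped: %d member(s) present, min_size=%d",
                name, len(hits), min_size,
            )
            continue
        mask = np.isin(np.array(matrix.ion_ids), hits)
        member_masks.append(mask)
        names.append(name)
        sizes.append(len(hits))
    if not member_masks:
        return pd.DataFrame(
            columns=["pathway", "es", "nes", "p", "q", "n_members", "n_perm", "seed"]
        )

    es_obs = np.array(
        [
            _es_from_order(t_obs, order_obs, mask, weight_p)
            for mask in member_masks
        ]
    )

    if null == "sample":
        # permuted group labels: re-rank per shuffle (vectorized over perms)
        perm = np.argsort(rng.random((n_perm, n)), axis=1, kind="stable")
        sel = np.zeros((n_perm, n))
        np.put_along_axis(sel, perm[:, :n_a], 1.0, axis=1)
        sq = log**2
        s1 = sel @ log.T  # (n_perm, n_ions) group-A sums
        q1 = sel @ sq.T
        s_tot, q_tot = log.sum(axis=1), sq.sum(axis=1)
        n_b = n - n_a
        m1, m2 = s1 / n_a, (s_tot - s1) / n_b
        v1 = (q1 - n_a * m1**2) / (n_a - 1)
        v2 = (q_tot - q1 - n_b * m2**2) / (n_b - 1)
        se = np.sqrt(v1 / n_a + v2 / n_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(se > 0, (m1 - m2) / se, 0.0)
        order_null = np.argsort(-t_null, axis=1, kind="stable")
        es_null = np.empty((len(names), n_perm))
        for k, mask in enumerate(member_masks):
            es_null[k] = _es_many(t_null, order_null, mask, weight_p)
    elif null == "metabolite":
        es_null = np.empty((len(names), n_perm))
        for k, (mask, size) in enumerate(zip(member_masks, sizes)):
            traces = np.empty(n_perm)
            for b in range(n_perm):
                rand_mask = np.zeros(n_ions, dtype=bool)
                rand_mask[rng.choice(n_ions, size, replace=False)] = True
                traces[b] = _es_from_order(t_obs, order_obs, rand_mask, weight_p)
            es_null[k] = traces
    else:
        raise InputError(f"unknown null type {null!r}")

    rows = []
    for k, name in enumerate(names):
        null_k = es_null[k]
        p = float((np.sum(np.abs(null_k) >= abs(es_obs[k]) - 1e-12) + 1) / (n_perm + 1))
        same_sign = null_k[np.sign(null_k) == np.sign(es_obs[k])]
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null_k).mean()
        nes = es_obs[k] / denom if denom > 0 else 0.0
        rows.append(
            {"pathway": name, "es": float(es_obs[k]), "nes": float(nes), "p": p,
             "n_members": sizes[k], "n_perm": n_perm, "seed": seed}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["pathway", "es", "nes", "p", "q", "n_members", "n_perm", "seed"]]


def _es_from_order(scores, order, mask, weight_p) -> float:
    trace = _running_sum(scores[order], mask[order], weight_p)
    return float(trace[np.argmax(np.abs(trace))])


def _es_many(t_null, order_null, mask, weight_p) -> np.ndarray:
    """ES per permutation, vectorized across the permutation axis."""
    scores = np.take_along_axis(t_null, order_null, axis=1)
    member = mask[order_null]
    n = mask.size
    n_mem = int(mask.sum())
    w = np.where(member, np.abs(scores) ** weight_p, 0.0)
    denom = w.sum(axis=1, keepdims=True)
    # all-zero member scores in a permutation: equal steps fallback
    flat = denom[:, 0] == 0.0
    if flat.any():
        w[flat] = member[flat].astype(float)
        denom[flat, 0] = n_mem
    step = w / denom - (~member) / (n - n_mem)
    run = np.cumsum(step, axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(run.shape[0]), idx]
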