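"""Paired comparison of residue packing between two conformers of a chain.

Given residue-level OSP tables for two structures of the same chain (say, an
experimental structure *a* and a computed model *b*), this module

* pairs residues 1:1 on (chain, res_seq, icode, res_name), reporting —
  never silently dropping — residues present on only one side;
* tests the paired OSP shift with a two-sided Wilcoxon signed-rank test
  (exact null for n <= 25, normal approximation above) and a paired
  Cohen's d = mean(diff) / sd(diff);
* compares dispersions via the standard-deviation gap sd_b - sd_a; and
* ranks residues by how much each one drives that dispersion difference,
  using the jackknife (leave-one-out) influence on the SD statistic, with
  the analytic influence function available as an alternative mode.

Residues whose influence score exceeds median + k * MAD of all scores
(k = 3 by default) are flagged as *influential* — the dispersive residues.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .metrics import ResiduePacking

__all__ = [
    "PairedResidueOSP",
    "PairingResult",
    "ComparisonReport",
    "pair_residues",
    "wilcoxon_signed_rank_p",
    "paired_stats",
    "sd_influence",
    "flag_influential",
    "compare_structures",
]

Side = Literal["a", "b", "gap"]


@dataclasses.dataclass
class PairedResidueOSP:
    """One matched residue with OSP from each side."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    osp_a: float
    osp_b: float

    @property
    def diff(self) -> float:
        return self.osp_b - self.osp_a

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.res_seq, self.icode, self.res_name)


@dataclasses.dataclass
class PairingResult:
    """1:1 pairing plus the residues that could not be matched."""

    pairs: list[PairedResidueOSP]
    unmatched_a: list[tuple[str, int, str, str]]
    unmatched_b: list[tuple[str, int, str, str]]


def pair_residues(
    a: Sequence[ResiduePacking], b: Sequence[ResiduePacking]
) -> PairingResult:
    """Match residues on (chain, res_seq, icode, res_name), ordered by position.

    A residue with the same number but a different name on the two sides is
    excluded from the pairs and reported on both unmatched lists.
    """
    map_a = {r.residue_key: r for r in a}
    map_b = {r.residue_key: r for r in b}
    pairs = [
        PairedResidueOSP(
            chain_id=ra.chain_id,
            res_seq=ra.res_seq,
            icode=ra.icode,
            res_name=ra.res_name,
            osp_a=ra.osp,
            osp_b=map_b[key].osp,
        )
        for key, ra in map_a.items()
        if key in map_b
    ]
    pairs.sort(key=lambda p: (p.chain_id, p.res_seq, p.icode))
    if not pairs:
        raise ValueError("no residues could be paired between the two structures")
    unmatched_a = sorted(k for k in map_a if k not in map_b)
    unmatched_b = sorted(k for k in map_b if k not in map_a)
    return PairingResult(pairs, unmatched_a, unmatched_b)


def wilcoxon_signed_rank_p(diffs: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Zero differences are dropped (Wilcoxon's original convention) and tied
    absolute differences get mid-ranks.  For n <= ``exact_max_n`` the exact
    null distribution of the positive-rank sum is computed by dynamic
    programming over the 2^n equiprobable sign assignments (valid with
    mid-rank ties); larger n uses the tie-corrected normal approximation.
    All differences zero gives p = 1 by convention.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # doubled ranks are integers even with mid-rank ties
        r2 = np.rint(2.0 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts += shifted
        w2 = int(round(2.0 * w_plus))
        denom = 2.0 ** n
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", correction=False, method="approx"
    )
    return float(res.pvalue)


def paired_stats(pairs: Sequence[PairedResidueOSP]) -> tuple[float, float]:
    """(wilcoxon_p, cohens_d) for the paired OSP differences b - a.

    Cohen's d (paired) is mean(diff) / sd(diff, n-1).  All-zero differences
    give (1.0, 0.0) by convention; zero sd with a nonzero mean gives a
    signed infinite d.
    """
    if len(pairs) < 2:
        raise ValueError("paired_stats requires at least 2 pairs")
    diffs = np.array([p.diff for p in pairs])
    if np.all(diffs == 0.0):
        return 1.0, 0.0
    p = wilcoxon_signed_rank_p(diffs)
    sd = float(diffs.std(ddof=1))
    mean = float(diffs.mean())
    if sd == 0.0:
        d = math.copysign(math.inf, mean) if mean != 0.0 else 0.0
    else:
        d = mean / sd
    return p, d


def _sd_stat(osp_a: np.ndarray, osp_b: np.ndarray, side: Side) -> float:
    if side == "a":
        return float(osp_a.std(ddof=1))
    if side == "b":
        return float(osp_b.std(ddof=1))
    if side == "gap":
        return float(osp_b.std(ddof=1) - osp_a.std(ddof=1))
    raise ValueError(f"side must be 'a', 'b' or 'gap', got {side!r}")


def sd_influence(
    pairs: Sequence[PairedResidueOSP],
    side: Side = "gap",
    mode: Literal["jackknife", "analytic"] = "jackknife",
) -> np.ndarray:
    """Per-residue influence on the dispersion statistic.

    ``jackknife`` (default): score_i = T(all pairs) - T(without pair i),
    where T is sd_a, sd_b, or the gap sd_b - sd_a depending on ``side``.  A
    large positive gap score marks a residue that inflates the b-side excess
    dispersion.

    ``analytic``: the influence function of the standard deviation,
    IF(x) = ((x - mu)^2 - sigma^2) / (2 sigma), evaluated per observation
    (differenced across sides for ``side='gap'``).  The jackknife scores
    approximate IF/(n-1); only the ranking is comparable across modes.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError("sd_influence requires at least 3 pairs")
    osp_a = np.array([p.osp_a for p in pairs])
    osp_b = np.array([p.osp_b for p in pairs])
    if mode == "jackknife":
        full = _sd_stat(osp_a, osp_b, side)
        mask = np.ones(n, dtype=bool)
        scores = np.empty(n)
        for i in range(n):
            mask[i] = False
            scores[i] = full - _sd_stat(osp_a[mask], osp_b[mask], side)
            mask[i] = True
        return scores
    if mode == "analytic":
        def per_obs(x: np.ndarray) -> np.ndarray:
            mu, sigma = x.mean(), x.std(ddof=1)
            if sigma == 0.0:
                return np.zeros_like(x)
            return ((x - mu) ** 2 - sigma**2) / (2.0 * sigma)

        if side == "a":
            return per_obs(osp_a)
        if side == "b":
            return per_obs(osp_b)
        if side == "gap":
            return per_obs(osp_b) - per_obs(osp_a)
        raise ValueError(f"side must be 'a', 'b' or 'gap', got {side!r}")
    raise ValueError(f"mode must be 'jackknife' or 'analytic', got {mode!r}")


def flag_influential(scores: np.ndarray, mad_k: float = 3.0) -> np.ndarray:
    """Boolean mask of scores above median + mad_k * MAD (a robust outlier rule).

    With all scores equal the MAD is zero and nothing exceeds the median, so
    the flagged set is empty; the rule is monotone in ``mad_k``.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("influence scores must be finite")
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    return scores > med + mad_k * mad


@dataclasses.dataclass
class ComparisonReport:
    """Paired OSP comparison between two structures of the same chain."""

    id_a: str
    id_b: str
    n_pairs: int
    n_unmatched_a: int
    n_unmatched_b: int
    mean_osp_a: float
    mean_osp_b: float
    sd_osp_a: float
    sd_osp_b: float
    wilcoxon_p: float
    cohens_d: float
    sd_gap: float  # sd_b - sd_a
    side: str
    mad_k: float
    pairs: list[PairedResidueOSP]
    influence: np.ndarray
    flagged: np.ndarray  # boolean, aligned with pairs

    @property
    def influential(self) -> list[tuple[str, int, str, str]]:
        """Residue keys of flagged (dispersion-driving) residues."""
        return [p.residue_key for p, f in zip(self.pairs, self.flagged) if f]

    @property
    def flagged_fraction(self) -> float:
        return float(np.mean(self.flagged)) if self.n_pairs else 0.0

    def influence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [p.chain_id for p in self.pairs],
                "res_seq": [p.res_seq for p in self.pairs],
                "res_name": [p.res_name for p in self.pairs],
                "osp_a": [p.osp_a for p in self.pairs],
                "osp_b": [p.osp_b for p in self.pairs],
                "diff": [p.diff for p in self.pairs],
                "influence": self.influence,
                "flagged": self.flagged,
            }
        )

    def to_dict(self) -> dict:
        return {
            "id_a": self.id_a,
            "id_b": self.id_b,
            "n_pairs": self.n_pairs,
            "n_unmatched_a": self.n_unmatched_a,
            "n_unmatched_b": self.n_unmatched_b,
            "mean_osp_a": self.mean_osp_a,
            "mean_osp_b": self.mean_osp_b,
            "sd_osp_a": self.sd_osp_a,
            "sd_osp_b": self.sd_osp_b,
            "wilcoxon_p": self.wilcoxon_p,
            "cohens_d": self.cohens_d,
            "sd_gap": self.sd_gap,
            "side": self.side,
            "mad_k": self.mad_k,
            "n_influential": int(np.sum(self.flagged)),
            "influential": [
                {"chain": k[0], "res_seq": k[1], "icode": k[2], "res_name": k[3]}
                for k in self.influential
            ],
        }


def compare_structures(
    residues_a: Sequence[ResiduePacking],
    residues_b: Sequence[ResiduePacking],
    id_a: str = "a",
    id_b: str = "b",
    side: Side = "gap",
    mad_k: float = 3.0,
    influence_mode: Literal["jackknife", "analytic"] = "jackknife",
) -> ComparisonReport:
    """Full paired comparison from two residue packing tables."""
    pairing = pair_residues(residues_a, residues_b)
    pairs = pairing.pairs
    osp_a = np.array([p.osp_a for p in pairs])
    osp_b = np.array([p.osp_b for p in pairs])
    wilcoxon_p, cohens_d = paired_stats(pairs)
    if len(pairs) >= 3:
        influence = sd_influence(pairs, side=side, mode=influence_mode)
        flagged = flag_influential(influence, mad_k=mad_k)
    else:
        influence = np.zeros(len(pairs))
        flagged = np.zeros(len(pairs), dtype=bool)
    return ComparisonReport(
        id_a=id_a,
        id_b=id_b,
        n_pairs=len(pairs),
        n_unmatched_a=len(pairing.unmatched_a),
        n_unmatched_b=len(pairing.unmatched_b),
        mean_osp_a=float(osp_a.mean()),
        mean_osp_b=float(osp_b.mean()),
        sd_osp_a=float(osp_a.std(ddof=1)) if len(pairs) > 1 else 0.0,
        sd_osp_b=float(osp_b.std(ddof=1)) if len(pairs) > 1 else 0.0,
        wilcoxon_p=wilcoxon_p,
        cohens_d=cohens_d,
        sd_gap=(
            float(osp_b.std(ddof=1) - osp_a.std(ddof=1)) if len(pairs) > 1 else 0.0
        ),
        side=side,
        mad_k=mad_k,
        pairs=pairs,
        influence=influence,
        flagged=flagged,
    )
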