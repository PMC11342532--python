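"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated from 3x3 joint dosage tables by
an EM algorithm that resolves the double-heterozygote phase ambiguity (the only
unobserved phase under Hardy-Weinberg random pairing).  From the four haplotype
frequencies the standard LD summaries are derived:

    D   = f(AB) - f(A) f(B)
    D'  = |D| / Dmax
    r^2 = D^2 / (f(A) f(a) f(B) f(b))

where ``A``/``a`` are the effect/other alleles at locus 1 and ``B``/``b`` at
locus 2.  The EM log-likelihood is monotone non-decreasing; a perturbed restart
guards against the symmetric saddle point that arises when every subject is a
double heterozygote.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LdPairResult",
    "two_locus_table",
    "em_haplotype_freqs",
    "ld_stats",
    "ld_pair",
    "ld_all_pairs",
    "genotype_table_loglik",
]

#: reporting-convenience label only; not a haplotype-block definition
STRONG_LD_DPRIME = 0.8
STRONG_LD_R2 = 0.5


@dataclass
class LdPairResult:
    snp1: str
    snp2: str
    #: haplotype frequencies in order (AB, Ab, aB, ab)
    hap_freqs: tuple[float, float, float, float]
    d: float
    d_prime: float
    r2: float
    loglik: float
    n_iter: int
    n: int
    strong_ld: bool
    defined: bool = True


def two_locus_table(dosage1, dosage2) -> np.ndarray:
    """3x3 joint genotype count table from two aligned dosage vectors."""
    g1 = np.asarray(dosage1)
    g2 = np.asarray(dosage2)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must be aligned")
    ok = np.isfinite(g1.astype(float)) & np.isfinite(g2.astype(float))
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    t = np.zeros((3, 3), dtype=int)
    for i, j in zip(g1, g2):
        t[i, j] += 1
    return t


def genotype_table_loglik(table: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 dosage table given hap freqs (AB,Ab,aB,ab)."""
    fab, fAb, faB, fabq = float(f[0]), float(f[1]), float(f[2]), float(f[3])
    p = np.array(
        [
            [fabq**2, 2 * faB * fabq, faB**2],
            [2 * fAb * fabq, 2 * fab * fabq + 2 * fAb * faB, 2 * fab * faB],
            [fAb**2, 2 * fab * fAb, fab**2],
        ]
    )
    # row index = copies of A, col index = copies of B
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(table > 0, table * np.log(np.maximum(p, 1e-300)), 0.0)
    return float(ll.sum())


def _em_once(table: np.ndarray, f0: np.ndarray, tol: float, max_iter: int):
    """Run EM from one start; returns (freqs, loglik, iterations)."""
    n = table.sum()
    t = table.astype(float)
    # phase-known haplotype counts (everything except the double heterozygote)
    base = np.array(
        [
            2 * t[2, 2] + t[2, 1] + t[1, 2],  # AB
            2 * t[2, 0] + t[2, 1] + t[1, 0],  # Ab
            2 * t[0, 2] + t[0, 1] + t[1, 2],  # aB
            2 * t[0, 0] + t[0, 1] + t[1, 0],  # ab
        ]
    )
    n_dh = t[1, 1]
    f = f0.copy()
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        w = 0.5 if coup + rep == 0 else coup / (coup + rep)
        counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        f_new = counts / (2 * n)
        ll = genotype_table_loglik(table, f_new)
        if ll < ll_prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        delta = np.abs(f_new - f).max()
        f = f_new
        ll_prev = ll
        if delta < tol or n_dh == 0:  # phase fully observed: M-step is exact
            break
    return f, ll_prev, it


def em_haplotype_freqs(
    table, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, float, int]:
    """EM haplotype-frequency estimate for a 3x3 two-locus dosage table.

    Row index = copies of allele A at locus 1, column = copies of B at locus 2.
    Starts from linkage equilibrium (products of observed allele frequencies)
    plus one coupling-perturbed restart; the higher-likelihood solution wins.
    Returns ``(freqs[AB, Ab, aB, ab], loglik, iterations)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3) or (t < 0).any():
        raise ValueError("expected a 3x3 non-negative count table")
    n = t.sum()
    if n < 1:
        raise ValueError("empty table")
    p_a = (2 * t[2, :].sum() + t[1, :].sum()) / (2 * n)  # freq of A
    p_b = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)  # freq of B
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        # monomorphic locus: no phase ambiguity, D = 0 by convention
        f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
        return f, genotype_table_loglik(t, f), 0
    le = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    eps = 0.5 * min(le.min(), 0.02)
    perturbed = le + np.array([eps, -eps, -eps, eps])  # nudge toward coupling
    best = None
    for f0 in (le, perturbed):
        f, ll, it = _em_once(t, f0, tol, max_iter)
        if best is None or ll > best[1] + 1e-12:
            best = (f, ll, it)
    return best


def ld_stats(hap_freqs) -> tuple[float, float, float]:
    """D, D', r^2 from haplotype frequencies ordered (AB, Ab, aB, ab)."""
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,) or (f < -1e-12).any() or abs(f.sum() - 1) > 1e-9:
        raise ValueError("haplotype frequencies must be 4 non-negative values summing to 1")
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    q_a, q_b = 1 - p_a, 1 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0:
        raise ValueError("D' and r^2 undefined when an allele frequency is 0")
    d = f[0] - p_a * p_b
    if d > 0:
        dmax = min(p_a * q_b, q_a * p_b)
    elif d < 0:
        dmax = min(p_a * p_b, q_a * q_b)
    else:
        return 0.0, 0.0, 0.0
    d_prime = abs(d) / dmax
    r2 = d**2 / (p_a * q_a * p_b * q_b)
    return float(d), float(d_prime), float(r2)


def ld_pair(
    cohort: pd.DataFrame,
    snp1: str,
    snp2: str,
    group: str = "control",
    status_col: str = "status",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LdPairResult:
    """Pairwise LD between two dosage columns of a cohort table.

    ``group`` is ``control`` (default; the usual LD reference set), ``case`` or
    ``all``.
    """
    if group == "all":
        sub = cohort
    elif group in ("case", "control"):
        sub = cohort[cohort[status_col] == (1 if group == "case" else 0)]
    else:
        raise ValueError("group must be 'case', 'control' or 'all'")
    table = two_locus_table(sub[snp1], sub[snp2])
    f, ll, it = em_haplotype_freqs(table, tol=tol, max_iter=max_iter)
    try:
        d, dp, r2 = ld_stats(f)
        defined = True
    except ValueError:
        d, dp, r2, defined = 0.0, float("nan"), float("nan"), False
    return LdPairResult(
        snp1=snp1,
        snp2=snp2,
        hap_freqs=tuple(float(x) for x in f),
        d=d,
        d_prime=dp,
        r2=r2,
        loglik=ll,
        n_iter=it,
        n=int(table.sum()),
        strong_ld=bool(defined and dp >= STRONG_LD_DPRIME and r2 >= STRONG_LD_R2),
        defined=defined,
    )


def ld_all_pairs(cohort: pd.DataFrame, snp_ids, group: str = "control", **kw) -> pd.DataFrame:
    """LD summary for every SNP pair; one row per pair with D, D', r^2, n."""
    rows = []
    for s1, s2 in itertools.combinations(snp_ids, 2):
        r = ld_pair(cohort, s1, s2, group=group, **kw)
        rows.append((r.snp1, r.snp2, r.d, r.d_prime, r.r2, r.n, r.strong_ld))
    return pd.DataFrame(rows, columns=["snp1", "snp2", "D", "D_prime", "r2", "n", "strong_ld"])
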