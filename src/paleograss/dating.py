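"""Ks estimation, molecular dating and Ks-distribution mixture modelling.

Synonymous divergence (Ks) between a pair of coding sequences is estimated
with the Nei-Gojobori (1986) counting method with Jukes-Cantor correction:
per-codon synonymous site fractions are averaged over both sequences,
synonymous differences between differing codons are averaged over all
minimal substitution paths (equal path weighting, paths through stop codons
excluded when any stop-free path exists), and

    ps = Sd / S,    Ks = -(3/4) * ln(1 - (4/3) * ps)

Ages follow the molecular clock T = Ks / (2 r) with r the synonymous
substitution rate per site per year (default 6.5e-9).  Gene pairs dating to
the 50-70 Ma window are ancient whole-genome-duplication (WGD) duplicates;
a separate, recent window captures lineage-specific neopolyploidy.

The Ks distribution of all paralog pairs of a genome is modelled as a
mixture of log-normal components (Gaussian EM on ln Ks); the component
count is chosen by the Bayesian information criterion, which distinguishes
single-WGD genomes (one component) from genomes with superimposed recent
WGDs (two components, the maize-like bimodal profile).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"
_CODON_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


class MalformedInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class DatingParams:
    r: float = 6.5e-9  # substitutions / synonymous site / year
    wgd_window_mya: tuple[float, float] = (50.0, 70.0)
    recent_window_mya: tuple[float, float] = (2.0, 20.0)
    ks_max: float = 3.0  # saturation cutoff

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.wgd_window_mya[0] >= self.wgd_window_mya[1]:
            raise ValueError("T_min must be < T_max")


# ---------------------------------------------------------------------------
# NG86 codon machinery
# ---------------------------------------------------------------------------

def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon: per position, the fraction of the
    three alternative nucleotides that give a non-stop codon with the same
    amino acid."""
    aa = _CODON_AA.get(codon)
    if aa is None:
        raise MalformedInputError(f"stop or invalid codon {codon!r} in sequence")
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _CODON_AA[alt] == aa:
                s += 1.0 / 3.0
    return s


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two
    codons over all minimal substitution paths, weighting paths equally.
    Paths passing through a stop codon are excluded unless every path does,
    in which case stop steps count as nonsynonymous."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> Optional[tuple[float, float]]:
        cur, sd, nd = c1, 0.0, 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                return None
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff)]
    valid = [r for r in results if r is not None]
    if not valid:
        # all paths blocked by stops: count the blocked steps as nonsynonymous
        valid = [(0.0, float(len(diff)))]
    sd = sum(r[0] for r in valid) / len(valid)
    nd = sum(r[1] for r in valid) / len(valid)
    return sd, nd


_SYN_CACHE: dict[str, float] = {}
_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def estimate_ks(seq1: str, seq2: str) -> float:
    """NG86 Ks for a gap-free aligned codon pair.

    Returns ``nan`` when the Jukes-Cantor correction is undefined
    (ps >= 3/4, saturated).  Columns with gaps should be removed upstream;
    any codon containing a non-ACGT character is dropped from the count.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise MalformedInputError("aligned sequences differ in length")
    if len(seq1) % 3:
        raise MalformedInputError("sequence length is not a multiple of 3")

    s_sites = 0.0
    sd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(b not in _BASES for b in c1 + c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            raise MalformedInputError("internal stop codon")
        for c in (c1, c2):
            if c not in _SYN_CACHE:
                _SYN_CACHE[c] = _syn_fraction(c)
        s_sites += 0.5 * (_SYN_CACHE[c1] + _SYN_CACHE[c2])
        key = (c1, c2)
        if key not in _PATH_CACHE:
            _PATH_CACHE[key] = _path_counts(c1, c2)
        sd += _PATH_CACHE[key][0]
        n_codons += 1
    if n_codons == 0 or s_sites == 0:
        raise MalformedInputError("no scorable codons")
    ps = sd / s_sites
    arg = 1.0 - (4.0 / 3.0) * ps
    if arg <= 0:
        return math.nan
    return -0.75 * math.log(arg)


def is_saturated(ks: float) -> bool:
    return not math.isfinite(ks)


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

def date_pair(ks: float, params: DatingParams = DatingParams()) -> float:
    """Age in Myr from Ks via T = Ks / 2r.  Saturated Ks dates to nan."""
    if not math.isfinite(ks):
        return math.nan
    if ks < 0:
        raise MalformedInputError("negative Ks")
    return ks / (2.0 * params.r) / 1e6


def label_wgd_pairs(
    ks_values: Sequence[float],
    params: DatingParams = DatingParams(),
    model: Optional["KsMixtureModel"] = None,
) -> list[str]:
    """Label each pair ``ancient_wgd`` / ``recent_wgd`` / ``other``.

    Default rule is windowing on T = Ks/2r (ancient window inclusive on
    both endpoints).  When a fitted mixture model is supplied, labels come
    from maximum-posterior component assignment instead: the component with
    the largest mean is ``ancient_wgd``, the others ``recent_wgd``.
    """
    if model is not None:
        labels = []
        order = np.argsort([m for _, m, _ in model.components])
        ancient_comp = order[-1]
        for ks in ks_values:
            if not math.isfinite(ks) or ks <= 0:
                labels.append("other")
                continue
            post = model.responsibilities(np.array([math.log(ks)]))[0]
            labels.append("ancient_wgd" if int(np.argmax(post)) == ancient_comp else "recent_wgd")
        return labels

    lo, hi = params.wgd_window_mya
    rlo, rhi = params.recent_window_mya
    out = []
    for ks in ks_values:
        t = date_pair(ks, params)
        if math.isnan(t):
            out.append("other")
        elif lo <= t <= hi:
            out.append("ancient_wgd")
        elif rlo <= t <= rhi:
            out.append("recent_wgd")
        else:
            out.append("other")
    return out


# ---------------------------------------------------------------------------
# log-normal mixture via EM, BIC model selection
# ---------------------------------------------------------------------------

@dataclass
class KsMixtureModel:
    k: int
    components: list[tuple[float, float, float]]  # (weight, mean_lnKs, sd_lnKs)
    bic: float
    loglik: float
    n: int
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        logp = np.stack(
            [
                math.log(w) - 0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * ((x - mu) / sd) ** 2
                for w, mu, sd in self.components
            ],
            axis=1,
        )
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


_VAR_FLOOR = 1e-6  # sd floor 1e-3


def _kmeans_1d(x: np.ndarray, k: int, rng: np.random.Generator, iters: int = 25) -> np.ndarray:
    centers = rng.choice(x, size=k, replace=len(x) < k)
    centers = np.sort(centers)
    for _ in range(iters):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            if np.any(assign == j):
                new[j] = x[assign == j].mean()
        if np.allclose(new, centers):
            break
        centers = new
    return centers


def _em_fit(x: np.ndarray, k: int, rng: np.random.Generator, tol: float, max_iter: int):
    n = len(x)
    centers = _kmeans_1d(x, k, rng)
    mu = centers.astype(float)
    var = np.full(k, max(x.var(), _VAR_FLOOR))
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    trace: list[float] = []
    for _ in range(max_iter):
        logp = (
            np.log(w)[None, :]
            - 0.5 * math.log(2 * math.pi)
            - 0.5 * np.log(var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        # EM guarantee: the observed-data log-likelihood never decreases
        if ll < prev_ll - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        trace.append(ll)
        resp = np.exp(logp - norm[:, None])
        nk = resp.sum(axis=0) + 1e-300
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = np.maximum((resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk, _VAR_FLOOR)
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return prev_ll, w, mu, np.sqrt(var), trace


def fit_ks_mixture(
    ks_values: Sequence[float],
    k_range: Sequence[int] = (1, 2, 3, 4),
    params: DatingParams = DatingParams(),
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> KsMixtureModel:
    """Fit Gaussian mixtures on ln Ks for each k and return the minimum-BIC model.

    Ks values outside (0, ks_max] are removed first (zero/negative and
    saturated values carry no dating signal).  BIC = -2 logLik + (3k-1) ln n
    with the weight-sum constraint accounted for.  EM uses k-means
    initialisation, ``n_restarts`` seeded restarts and a variance floor.
    """
    arr = np.asarray([k for k in ks_values if math.isfinite(k)], dtype=float)
    arr = arr[(arr > 0) & (arr <= params.ks_max)]
    if len(arr) < 30:
        raise InsufficientDataError(f"only {len(arr)} usable Ks values (need >= 30)")
    x = np.log(arr)
    n = len(x)

    best: Optional[KsMixtureModel] = None
    ss = np.random.SeedSequence(seed)
    for k in k_range:
        best_ll = -np.inf
        best_fit = None
        for child in ss.spawn(n_restarts):
            rng = np.random.default_rng(child)
            ll, w, mu, sd, trace = _em_fit(x, k, rng, tol, max_iter)
            if ll > best_ll:
                best_ll, best_fit = ll, (w, mu, sd, trace)
        w, mu, sd, trace = best_fit
        bic = -2.0 * best_ll + (3 * k - 1) * math.log(n)
        order = np.argsort(mu)
        comps = [(float(w[i]), float(mu[i]), float(sd[i])) for i in order]
        model = KsMixtureModel(k=k, components=comps, bic=bic, loglik=best_ll, n=n, loglik_trace=trace)
        if best is None or model.bic < best.bic:
            best = model
    assert best is not None
    return best
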