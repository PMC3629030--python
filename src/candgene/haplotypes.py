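"""Sliding-window haplotype frequencies by EM and haplotype trend regression.

Haplotype frequencies over short windows of biallelic SNPs are estimated from
unphased genotypes by EM over phase ambiguity; each individual receives
posterior expected haplotype counts ("dosages") which are used as regressors
for the trait — the trend-regression construction — with window significance
from a permutation F test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

_EM_TOL = 1e-8
_EM_MAX_ITER = 500


class HaplotypeError(ValueError):
    pass


@dataclass
class WindowHaplotypes:
    """EM-estimated haplotype frequencies and per-individual dosages for a
    window of consecutive SNPs."""

    window: tuple[int, ...]                 # SNP indices
    snp_ids: tuple[str, ...]
    haplotypes: list[str]                   # e.g. "010" (counted-allele coding)
    frequencies: np.ndarray                 # len = n_haplotypes, sums to 1
    dosage_matrix: np.ndarray               # n_individuals × n_haplotypes
    individual_mask: np.ndarray             # individuals with complete genotypes
    log_likelihood: float
    n_iterations: int
    ll_trace: tuple = ()

    def frequency_of(self, hap: str) -> float:
        return float(self.frequencies[self.haplotypes.index(hap)])


def _compatible_pairs(genotype: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All (h1, h2) haplotype pairs consistent with an unphased genotype."""
    het = [k for k, g in enumerate(genotype) if g == 1]
    fixed = [g // 2 for g in genotype]  # 0→0, 2→1 (het filled below)
    pairs = []
    for phase in itertools.product((0, 1), repeat=len(het)):
        h1, h2 = list(fixed), list(fixed)
        for k, b in zip(het, phase):
            h1[k], h2[k] = b, 1 - b
        pairs.append((tuple(h1), tuple(h2)))
    # deduplicate unordered pairs
    seen, out = set(), []
    for h1, h2 in pairs:
        key = (min(h1, h2), max(h1, h2))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def em_window_haplotypes(
    genotypes: GenotypeMatrix, window: tuple[int, ...] | list[int]
) -> WindowHaplotypes:
    """EM haplotype frequency estimation over a SNP window.

    Individuals missing any window genotype are excluded (their dosage rows
    are zero and flagged in ``individual_mask``).  Initialisation is at
    linkage equilibrium; convergence at max frequency change < 1e-8.
    """
    window = tuple(int(j) for j in window)
    w = len(window)
    G = genotypes.dosages[:, window]
    mask = np.isfinite(G).all(axis=1)
    if not mask.any():
        raise HaplotypeError("no individual has complete genotypes in window")
    Gc = G[mask].astype(int)
    n_ind = Gc.shape[0]

    haplotypes = ["".join(map(str, h))
                  for h in itertools.product((0, 1), repeat=w)]
    hap_index = {tuple(int(c) for c in h): k for k, h in enumerate(haplotypes)}
    n_h = len(haplotypes)

    # linkage-equilibrium initialisation from marginal allele frequencies
    p = Gc.mean(axis=0) / 2.0
    freqs = np.array([
        np.prod([p[k] if int(h[k]) else 1 - p[k] for k in range(w)])
        for h in haplotypes
    ])
    freqs = np.maximum(freqs, 1e-12)
    freqs /= freqs.sum()

    # group individuals by genotype pattern
    patterns: dict[tuple[int, ...], int] = {}
    counts: list[int] = []
    pair_lists: list[list[tuple[int, int]]] = []
    row_of: np.ndarray = np.empty(n_ind, dtype=int)
    for i, g in enumerate(map(tuple, Gc)):
        if g not in patterns:
            patterns[g] = len(counts)
            counts.append(0)
            pair_lists.append([(hap_index[h1], hap_index[h2])
                               for h1, h2 in _compatible_pairs(g)])
        row_of[i] = patterns[g]
        counts[patterns[g]] += 1
    counts_arr = np.array(counts, dtype=float)

    ll = -np.inf
    it = 0
    trace: list[float] = []
    pattern_post: list[np.ndarray] = [np.empty(0)] * len(counts)
    for it in range(1, _EM_MAX_ITER + 1):
        new_counts = np.zeros(n_h)
        ll_new = 0.0
        for pat_i, pairs in enumerate(pair_lists):
            wts = np.array([
                (1.0 if a == b else 2.0) * freqs[a] * freqs[b]
                for a, b in pairs
            ])
            tot = wts.sum()
            if tot <= 0:
                wts = np.ones(len(pairs))
                tot = float(len(pairs))
            post = wts / tot
            pattern_post[pat_i] = post
            ll_new += counts_arr[pat_i] * np.log(max(tot, 1e-300))
            for (a, b), q in zip(pairs, post):
                new_counts[a] += counts_arr[pat_i] * q
                new_counts[b] += counts_arr[pat_i] * q
        new_freqs = new_counts / (2.0 * n_ind)
        delta = np.max(np.abs(new_freqs - freqs))
        freqs = new_freqs
        ll = ll_new
        trace.append(ll)
        if delta < _EM_TOL:
            break

    # posterior expected haplotype dosages per individual
    dosage = np.zeros((genotypes.n_individuals, n_h))
    comp_idx = np.flatnonzero(mask)
    for i, pat_i in zip(comp_idx, row_of):
        for (a, b), q in zip(pair_lists[pat_i], pattern_post[pat_i]):
            dosage[i, a] += q
            dosage[i, b] += q
    return WindowHaplotypes(
        window=window,
        snp_ids=tuple(genotypes.snp_ids[j] for j in window),
        haplotypes=haplotypes, frequencies=freqs, dosage_matrix=dosage,
        individual_mask=mask, log_likelihood=float(ll), n_iterations=it,
        ll_trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# haplotype trend regression
# ---------------------------------------------------------------------------

@dataclass
class HTRResult:
    """Haplotype-trend-regression result for one window × trait."""

    window: tuple[int, ...]
    snp_ids: tuple[str, ...]
    trait: str
    f_statistic: float
    p_perm: float
    r2_explained: float
    tested_haplotypes: list[tuple[str, float]]   # (haplotype, frequency)
    per_haplotype_p: dict[str, float] = field(default_factory=dict)


def _model_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of a centred design matrix;
    collinear columns are dropped (with a warning)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    r = int((s > tol).sum())
    if r < X.shape[1]:
        warnings.warn(f"dropped {X.shape[1] - r} collinear dosage column(s)")
    return U[:, :r]


def htr_test(
    y: np.ndarray,
    window_haps: WindowHaplotypes,
    freq_min: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
    trait: str = "trait",
) -> HTRResult:
    """Permutation F test of trait on haplotype dosages.

    Haplotypes with frequency > ``freq_min`` are tested; the most frequent is
    the reference (dropped) and rarer haplotypes are pooled out of the test.
    p_perm = (1 + #{perm F ≥ observed}) / (1 + B) permuting the trait.
    """
    y = np.asarray(y, dtype=float)
    mask = window_haps.individual_mask & np.isfinite(y)
    yv = y[mask]
    n = len(yv)
    freqs = window_haps.frequencies
    passing = [k for k in range(len(freqs)) if freqs[k] > freq_min]
    if len(passing) < 2:
        raise HaplotypeError("fewer than 2 haplotypes pass the frequency filter")
    ref = passing[int(np.argmax(freqs[passing]))]
    test_cols = [k for k in passing if k != ref]
    X = window_haps.dosage_matrix[mask][:, test_cols]
    Xc = X - X.mean(axis=0)
    yc = yv - yv.mean()
    basis = _model_basis(Xc)
    df1 = basis.shape[1]
    df2 = n - df1 - 1
    if df1 == 0 or df2 <= 0:
        raise HaplotypeError("degenerate design for trend regression")

    def f_of(Y: np.ndarray) -> np.ndarray:
        """F statistics for columns of centred trait matrix Y (n × B)."""
        ssm = (basis.T @ Y) ** 2
        ssm = ssm.sum(axis=0)
        sst = (Y ** 2).sum(axis=0)
        sse = np.maximum(sst - ssm, 1e-300)
        return (ssm / df1) / (sse / df2)

    f_obs = float(f_of(yc[:, None])[0])
    sst = float(yc @ yc)
    ssm_obs = float(((basis.T @ yc) ** 2).sum())
    r2 = 100.0 * ssm_obs / sst if sst > 0 else 0.0

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_permutations))
    for b in range(n_permutations):
        perms[:, b] = rng.permutation(yc)
    f_perm = f_of(perms)
    p_perm = float((1 + (f_perm >= f_obs - 1e-12).sum()) / (1 + n_permutations))

    per_hap_p = {}
    for k in test_cols:
        x = window_haps.dosage_matrix[mask][:, k]
        if np.std(x) == 0:
            continue
        slope, _, _, p_single, _ = stats.linregress(x, yv)
        per_hap_p[window_haps.haplotypes[k]] = float(p_single)

    tested = [(window_haps.haplotypes[k], float(freqs[k])) for k in passing]
    return HTRResult(
        window=window_haps.window, snp_ids=window_haps.snp_ids, trait=trait,
        f_statistic=f_obs, p_perm=p_perm, r2_explained=r2,
        tested_haplotypes=tested, per_haplotype_p=per_hap_p,
    )


def sliding_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    window: int = 3,
    freq_min: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
    significance_alpha: float = 0.05,
) -> pd.DataFrame:
    """Sliding-window haplotype trend regression over all traits.

    Tests the m − window + 1 consecutive windows per trait and returns a
    long-format table with window-level permutation p, R² and the
    significant haplotypes (per-haplotype p ≤ ``significance_alpha``) with
    their frequencies.
    """
    m = genotypes.n_snps
    if m < window:
        raise HaplotypeError(f"need ≥{window} SNPs")
    ids = list(genotypes.individuals)
    pheno = phenotypes.loc[ids]
    rows = []
    rng = np.random.default_rng(seed)
    for start in range(m - window + 1):
        win = tuple(range(start, start + window))
        try:
            wh = em_window_haplotypes(genotypes, win)
        except HaplotypeError as exc:
            warnings.warn(f"window {win}: {exc}")
            continue
        for trait in pheno.columns:
            y = pheno[trait].to_numpy(dtype=float)
            try:
                res = htr_test(y, wh, freq_min=freq_min,
                               n_permutations=n_permutations,
                               seed=int(rng.integers(2 ** 31)), trait=trait)
            except HaplotypeError:
                continue
            sig_haps = {h: p for h, p in res.per_haplotype_p.items()
                        if p <= significance_alpha}
            rows.append({
                "window_start": start,
                "window_snps": "|".join(res.snp_ids),
                "trait": trait,
                "p_perm": res.p_perm,
                "r2_explained": res.r2_explained,
                "significant": res.p_perm <= significance_alpha,
                "significant_haplotypes": ";".join(
                    f"{h}:{wh.frequency_of(h):.4f}" for h in sorted(sig_haps)),
            })
    return pd.DataFrame(rows)
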