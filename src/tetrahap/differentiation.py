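"""Among-population differentiation: F_ST, Rho, locus-wise F_ST,
private alleles, polyploid AMOVA and a neighbor-joining tree.

F_ST is Wright's fixation index ``(H_T - H_S)/H_T``.  Rho is the
ploidy-aware analogue ``(H_T - H_S)/(H_T - H_O (k-1)/k)``: subtracting a
fraction of the observed heterozygosity from the denominator removes the
part of within-population diversity that polysomic inheritance protects
from drift, which makes the statistic comparable between ploidy levels
and insensitive to double reduction.

Multi-locus values combine per-locus components as a ratio of sums
(sum of numerators over sum of denominators), the standard choice that
avoids instability at loci with tiny H_T; ``combine="mean"`` gives the
mean-of-ratios alternative.  Ensemble allele frequencies weight
populations equally, not by sample size.

The AMOVA is a two-level analysis on squared Euclidean distances between
individuals' concatenated allele-dosage vectors (an allele-count AMOVA);
significance of the among-population component comes from permuting
whole individuals among populations with population sizes preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from tetrahap.diversity import allele_frequencies, gene_diversity
from tetrahap.dosage import GenotypeMatrix
from tetrahap.madc_io import PopulationAssignment


@dataclass
class PairwiseMatrix:
    """Symmetric population x population differentiation matrix."""

    labels: list[str]
    values: np.ndarray
    statistic: str
    floored: list[tuple[str, str]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def mean_offdiagonal(self) -> float:
        m = self.values
        iu = np.triu_indices(len(self.labels), 1)
        return float(np.nanmean(m[iu]))


def fst(h_t: float, h_s: float) -> float:
    """Wright's fixation index ``(H_T - H_S)/H_T``; NaN when H_T = 0."""
    if h_t <= 0:
        return float("nan")
    return (h_t - h_s) / h_t


def rho(h_t: float, h_s: float, h_o: float, k: int = 4) -> float:
    """Ploidy-corrected differentiation
    ``(H_T - H_S)/(H_T - H_O (k-1)/k)``; NaN when the denominator is
    not positive."""
    denom = h_t - h_o * (k - 1) / k
    if denom <= 0:
        return float("nan")
    return (h_t - h_s) / denom


def _pop_locus_components(
    genotypes: GenotypeMatrix, pops: PopulationAssignment
) -> tuple[list[str], list[str], dict]:
    """Per population x locus: corrected H_S, mean H_O, frequency vector."""
    k = genotypes.ploidy
    labels = pops.population_labels()
    sample_pop = [pops.population_of(s) for s in genotypes.sample_ids]
    comp: dict[tuple[str, str], tuple[float, float, np.ndarray]] = {}
    for li, locus in enumerate(genotypes.locus_ids):
        for p in labels:
            tallies = np.zeros(len(genotypes.allele_ids[locus]))
            ho_sum, n_called = 0.0, 0
            for s, sp in enumerate(sample_pop):
                if sp != p:
                    continue
                d = genotypes.calls[s][li]
                if d is None:
                    continue
                tallies += d
                ho_sum += 1 - (d * (d - 1) / 2).sum() / (k * (k - 1) / 2)
                n_called += 1
            if n_called == 0:
                continue
            c = k * n_called
            freq = tallies / tallies.sum()
            hs = gene_diversity(freq, c) if c >= 2 else float("nan")
            comp[(p, locus)] = (hs, ho_sum / n_called, freq)
    return labels, list(genotypes.locus_ids), comp


def _ensemble_stat(
    pops_subset: list[str],
    loci: list[str],
    comp: dict,
    statistic: str,
    k: int,
    combine: str = "ratio_of_sums",
) -> float:
    """F_ST or Rho over a set of populations, combined across loci."""
    nums, dens = [], []
    for locus in loci:
        cells = [comp[(p, locus)] for p in pops_subset if (p, locus) in comp]
        if len(cells) < len(pops_subset):
            continue
        hs = float(np.mean([c[0] for c in cells]))
        ho = float(np.mean([c[1] for c in cells]))
        pbar = np.mean([c[2] for c in cells], axis=0)
        ht = gene_diversity(pbar)
        num = ht - hs
        den = ht if statistic == "fst" else ht - ho * (k - 1) / k
        nums.append(num)
        dens.append(den)
    if not nums:
        return float("nan")
    if combine == "mean":
        vals = [n / d for n, d in zip(nums, dens) if d > 0]
        return float(np.mean(vals)) if vals else float("nan")
    den_sum = float(np.sum(dens))
    if den_sum <= 0:
        return float("nan")
    return float(np.sum(nums)) / den_sum


def pairwise_differentiation(
    genotypes: GenotypeMatrix,
    pops: PopulationAssignment,
    statistic: str = "fst",
    combine: str = "ratio_of_sums",
) -> PairwiseMatrix:
    """Population x population F_ST or Rho matrix.

    For each pair: H_S = mean of the two within-population gene
    diversities, H_T from the pair's unweighted mean allele frequencies,
    H_O = pair mean observed heterozygosity; combined across loci per
    ``combine``.  Negative estimates are floored at 0 and flagged.
    """
    if statistic not in ("fst", "rho"):
        raise ValueError("statistic must be 'fst' or 'rho'")
    labels, loci, comp = _pop_locus_components(genotypes, pops)
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    n = len(labels)
    mat = np.zeros((n, n))
    floored = []
    for i in range(n):
        for j in range(i + 1, n):
            v = _ensemble_stat(
                [labels[i], labels[j]], loci, comp, statistic,
                genotypes.ploidy, combine,
            )
            if not np.isnan(v) and v < 0:
                floored.append((labels[i], labels[j]))
                v = 0.0
            mat[i, j] = mat[j, i] = v
    return PairwiseMatrix(labels, mat, statistic, floored)


def locus_fst(
    genotypes: GenotypeMatrix,
    pops: PopulationAssignment,
    large_effect: float = 0.2,
) -> pd.DataFrame:
    """Per-locus F_ST over all populations, with a flag for loci above
    the large-effect threshold.  Monomorphic loci get F_ST = 0."""
    labels, loci, comp = _pop_locus_components(genotypes, pops)
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    rows = []
    for locus in loci:
        cells = [comp[(p, locus)] for p in labels if (p, locus) in comp]
        if not cells:
            continue
        hs = float(np.mean([c[0] for c in cells]))
        pbar = np.mean([c[2] for c in cells], axis=0)
        ht = gene_diversity(pbar)
        v = 0.0 if ht <= 0 else min(1.0, max(0.0, (ht - hs) / ht))
        rows.append(
            {"locus": locus, "fst": v, "large_effect": v > large_effect}
        )
    return pd.DataFrame(rows)


def private_alleles(
    freqs: dict[str, dict[str, tuple[np.ndarray, int]]],
    allele_ids: dict[str, list[str]] | None = None,
    min_private_freq: float = 0.05,
) -> pd.DataFrame:
    """Alleles present in exactly one population with frequency above
    ``min_private_freq`` there.

    ``freqs`` is the mapping returned by
    :func:`tetrahap.diversity.allele_frequencies`.
    """
    pops_ = list(freqs)
    loci: dict[str, int] = {}
    for p in pops_:
        for locus, (vec, _c) in freqs[p].items():
            loci[locus] = len(vec)
    rows = []
    for locus, a in loci.items():
        for ai in range(a):
            carriers = [
                p for p in pops_
                if locus in freqs[p] and freqs[p][locus][0][ai] > 0
            ]
            if len(carriers) != 1:
                continue
            p = carriers[0]
            f = float(freqs[p][locus][0][ai])
            if f > min_private_freq:
                aid = (
                    allele_ids[locus][ai]
                    if allele_ids is not None
                    else f"{locus}:{ai}"
                )
                rows.append(
                    {
                        "locus": locus,
                        "allele_id": aid,
                        "population": p,
                        "frequency": f,
                    }
                )
    return pd.DataFrame(rows, columns=["locus", "allele_id", "population", "frequency"])


def _dosage_distance_sq(genotypes: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distance between individuals'
    concatenated dosage vectors, missing loci pairwise-deleted (distance
    rescaled by total/shared locus count)."""
    n = len(genotypes.sample_ids)
    L = len(genotypes.locus_ids)
    d2 = np.zeros((n, n))
    shared = np.zeros((n, n))
    for locus in genotypes.locus_ids:
        dt = genotypes.dosage_tensor(locus)
        ok = ~np.isnan(dt[:, 0])
        idx = np.where(ok)[0]
        sub = dt[idx]
        diff = sub[:, None, :] - sub[None, :, :]
        d2[np.ix_(idx, idx)] += np.einsum("ijk,ijk->ij", diff, diff)
        shared[np.ix_(idx, idx)] += 1
    if np.any(shared[np.triu_indices(n, 1)] == 0):
        raise ValueError("some individual pairs share no typed loci")
    return d2 * (L / shared)


def _copy_distance_sq(genotypes: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distance between one-hot allele-copy
    vectors (k rows per individual, grouped consecutively); 0 for equal
    alleles, 2 otherwise, summed over loci with pairwise deletion."""
    n = len(genotypes.sample_ids)
    k = genotypes.ploidy
    L = len(genotypes.locus_ids)
    nu = n * k
    d2 = np.zeros((nu, nu))
    shared = np.zeros((nu, nu))
    for li, locus in enumerate(genotypes.locus_ids):
        alleles = np.full(nu, -1, dtype=np.int64)
        for s in range(n):
            d = genotypes.calls[s][li]
            if d is None:
                continue
            copies = np.repeat(np.arange(len(d)), d)
            alleles[s * k : s * k + k] = copies
        ok = alleles >= 0
        okm = ok[:, None] & ok[None, :]
        neq = alleles[:, None] != alleles[None, :]
        d2 += 2.0 * (neq & okm)
        shared += okm
    if np.any(shared[np.triu_indices(nu, 1)] == 0):
        raise ValueError("some copy pairs share no typed loci")
    return d2 * (L / shared)


def _amova_ss(d2: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        if len(g) < 2:
            continue
        block = d2[np.ix_(g, g)]
        ss_within += block[np.triu_indices(len(g), 1)].sum() / len(g)
    return ss_total - ss_within, ss_within


def amova(
    genotypes: GenotypeMatrix,
    pops: PopulationAssignment,
    n_permutations: int = 1000,
    seed: int = 0,
    units: str = "copies",
) -> pd.DataFrame:
    """Two-level AMOVA (among populations vs within populations) with a
    permutation test on the among-population variance component.

    ``units="copies"`` (default) expands every individual into its
    ``k`` allele copies (one-hot vectors), the allele-count FST-type
    AMOVA whose %Var among populations estimates the nominal
    differentiation.  ``units="individuals"`` uses squared Euclidean
    distances between whole dosage vectors; because the among-population
    term then scales with ``k^2`` while the within term scales with
    ``k``, its %Var lands on the ploidy-corrected (Rho) scale, like the
    polyploid AMOVA of GenoDive.  Both permute whole individuals among
    populations with population sizes preserved.

    Returns a DataFrame with rows ``AP`` and ``AI/WP`` and columns
    ``df, SS, MS, variance, pct_var``; the permutation p-value and
    permutation count are in ``df.attrs``.
    """
    if units not in ("copies", "individuals"):
        raise ValueError("units must be 'copies' or 'individuals'")
    labels = pops.population_labels()
    sample_pop = np.array(
        [pops.population_of(s) for s in genotypes.sample_ids]
    )
    ind_groups = []
    for p in labels:
        g = np.where(sample_pop == p)[0]
        if len(g) < 2:
            warnings.warn(f"population {p} has <2 individuals; excluded")
            continue
        ind_groups.append(g)
    if len(ind_groups) < 2:
        raise ValueError("need >= 2 populations with >= 2 individuals")
    keep = np.concatenate(ind_groups)
    keep.sort()
    if len(keep) < len(sample_pop):
        remap = {old: new for new, old in enumerate(keep)}
        ind_groups = [np.array([remap[i] for i in g]) for g in ind_groups]
    sub = _subset_genotypes(genotypes, keep)
    k = sub.ploidy

    if units == "copies":
        d2 = _copy_distance_sq(sub)
        to_units = lambda g: (g[:, None] * k + np.arange(k)[None, :]).ravel()
    else:
        d2 = _dosage_distance_sq(sub)
        to_units = lambda g: g
    groups = [to_units(g) for g in ind_groups]

    n = d2.shape[0]
    P = len(groups)
    ss_among, ss_within = _amova_ss(d2, groups)
    df_among, df_within = P - 1, n - P
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sizes = np.array([len(g) for g in groups])
    n0 = (n - (sizes**2).sum() / n) / (P - 1)
    var_within = ms_within
    var_among_raw = (ms_among - ms_within) / n0
    flag_floored = var_among_raw < 0
    var_among = max(var_among_raw, 0.0)
    total = var_among + var_within
    pct_among = 100.0 * var_among / total if total > 0 else 0.0

    rng = np.random.default_rng(seed)
    ind_sizes = np.array([len(g) for g in ind_groups])
    n_ind = int(ind_sizes.sum())
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_ind)
        pgroups = []
        start = 0
        for sz in ind_sizes:
            pgroups.append(to_units(perm[start : start + sz]))
            start += sz
        ss_a, ss_w = _amova_ss(d2, pgroups)
        v_a = (ss_a / df_among - ss_w / df_within) / n0
        # compared against the raw (unfloored) observed component so the
        # test stays calibrated when the observed estimate is negative
        if v_a >= var_among_raw:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_permutations)

    out = pd.DataFrame(
        [
            {
                "stratum": "AP",
                "df": df_among,
                "SS": ss_among,
                "MS": ms_among,
                "variance": var_among,
                "pct_var": pct_among,
            },
            {
                "stratum": "AI/WP",
                "df": df_within,
                "SS": ss_within,
                "MS": ms_within,
                "variance": var_within,
                "pct_var": 100.0 - pct_among,
            },
        ]
    )
    out.attrs["p_value"] = p_value
    out.attrs["n_permutations"] = n_permutations
    out.attrs["among_floored"] = bool(flag_floored)
    return out


def _subset_genotypes(genotypes: GenotypeMatrix, rows) -> GenotypeMatrix:
    rows = list(rows)
    return GenotypeMatrix(
        sample_ids=[genotypes.sample_ids[i] for i in rows],
        locus_ids=genotypes.locus_ids,
        allele_ids=genotypes.allele_ids,
        calls=[genotypes.calls[i] for i in rows],
        ploidy=genotypes.ploidy,
        allele_sequences=genotypes.allele_sequences,
    )


def nj_tree(matrix: PairwiseMatrix | pd.DataFrame) -> str:
    """Saitou-Nei neighbor-joining tree from a differentiation matrix,
    returned as an unrooted newick string with branch lengths.

    Negative branch lengths are floored at 0 with the deficit
    transferred to the sibling edge.
    """
    if isinstance(matrix, PairwiseMatrix):
        labels, values = matrix.labels, matrix.values
    else:
        labels, values = list(matrix.index), matrix.to_numpy()
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    dm = DistanceMatrix(np.asarray(values, dtype=float), list(labels))
    tree = _skbio_nj(dm)
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            deficit = node.length
            node.length = 0.0
            if node.parent is not None:
                sibs = [c for c in node.parent.children if c is not node]
                if sibs and sibs[0].length is not None:
                    sibs[0].length += deficit
    return str(tree).strip()
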