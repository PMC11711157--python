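"""Tetraploid allele-dosage calling from amplicon read counts.

The caller is a Dirichlet-multinomial maximum-a-posteriori (MAP)
genotyper.  For a locus with ``A`` alleles and an individual of ploidy
``k``, every candidate dosage vector ``d`` (non-negative integers summing
to ``k``) is scored by

    log P(reads | d) + log P(d | prior)

where ``P(reads | d)`` is Dirichlet-multinomial with expected allele
proportions

    q_a = (1 - eps) * d_a / k + eps * (1 - d_a / k) / (A - 1)

(sequencing errors from carried alleles spread uniformly over the other
alleles) and overdispersion ``rho`` (``rho = 0`` degenerates to the
multinomial), and ``P(d | prior)`` is the multinomial(k, prior)
probability of drawing ``d`` allele copies under tetrasomic
Hardy-Weinberg at the prior allele frequencies.  Priors are iterated:
round one uses uniform frequencies, later rounds use per-population
frequencies recomputed from the current calls, which pulls ambiguous
read patterns toward the genotypes common in that population.

Dosages are reported as the MAP integer vector because every downstream
statistic here consumes discrete allele counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from tetrahap.madc_io import MADCTable, PopulationAssignment

DEFAULT_RHO_GRID = (0.0, 0.01, 0.02, 0.05, 0.1)


@dataclass
class DosageModel:
    """Parameters of the Dirichlet-multinomial dosage caller."""

    error_rate: float = 0.001
    overdispersion: float = 0.0
    n_prior_iterations: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion must be in [0, 1)")


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage calls.

    ``calls[s][l]`` is either ``None`` (missing) or an integer vector
    over the locus's allele list summing to the ploidy ``k``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    allele_ids: dict[str, list[str]]
    calls: list[list[np.ndarray | None]]
    ploidy: int = 4
    allele_sequences: dict[str, list[str]] = field(default_factory=dict)

    def locus_pos(self, locus: str) -> int:
        return self.locus_ids.index(locus)

    def dosage_tensor(self, locus: str) -> np.ndarray:
        """(n_samples, n_alleles) float array of dosages, NaN = missing."""
        li = self.locus_pos(locus)
        a = len(self.allele_ids[locus])
        out = np.full((len(self.sample_ids), a), np.nan)
        for s in range(len(self.sample_ids)):
            d = self.calls[s][li]
            if d is not None:
                out[s] = d
        return out

    def alt_dosage_matrix(self) -> np.ndarray:
        """(n_samples, n_loci) dosage of the first non-reference allele;
        for biallelic (target-SNP) matrices this is the 0..k alt dosage.
        Monomorphic loci yield 0; missing calls yield NaN."""
        out = np.full((len(self.sample_ids), len(self.locus_ids)), np.nan)
        for li, locus in enumerate(self.locus_ids):
            a = len(self.allele_ids[locus])
            for s in range(len(self.sample_ids)):
                d = self.calls[s][li]
                if d is not None:
                    out[s, li] = d[1] if a > 1 else 0.0
        return out

    def missing_rate(self) -> float:
        total = len(self.sample_ids) * len(self.locus_ids)
        miss = sum(c is None for row in self.calls for c in row)
        return miss / total if total else 0.0


def dosage_vectors(k: int, n_alleles: int) -> np.ndarray:
    """All C(k + A - 1, A - 1) dosage vectors with sum k, as an array
    sorted lexicographically descending (all-first-allele first)."""
    vecs = []
    for combo in combinations_with_replacement(range(n_alleles), k):
        v = np.bincount(combo, minlength=n_alleles)
        vecs.append(v)
    arr = np.unique(np.array(vecs, dtype=np.int64), axis=0)
    order = np.lexsort(arr.T[::-1])[::-1]
    return arr[order]


def expected_proportions(d: np.ndarray, k: int, eps: float) -> np.ndarray:
    """Error-adjusted expected read proportions for dosage vectors ``d``
    ((n_d, A) or (A,))."""
    d = np.atleast_2d(d).astype(float)
    a = d.shape[1]
    if a == 1:
        return np.ones_like(d)
    q = (1 - eps) * d / k + eps * (1 - d / k) / (a - 1)
    return q


def _read_loglik(counts: np.ndarray, q: np.ndarray, rho: float) -> np.ndarray:
    """Unnormalised log P(reads | d) for counts (n, A) against proportion
    rows q (n_d, A); returns (n, n_d).  The multinomial coefficient is
    constant in d and omitted."""
    counts = np.atleast_2d(counts).astype(float)
    if rho <= 0:
        logq = np.where(q > 0, np.log(np.maximum(q, 1e-300)), 0.0)
        ll = counts @ logq.T
        # impossible categories: q == 0 with reads present
        bad = (counts[:, None, :] > 0) & (q[None, :, :] <= 0)
        ll[bad.any(axis=2)] = -np.inf
        return ll
    alpha = q * (1 - rho) / rho  # (n_d, A)
    a0 = alpha.sum(axis=1)  # (n_d,)
    n_tot = counts.sum(axis=1)  # (n,)
    term0 = gammaln(a0)[None, :] - gammaln(a0[None, :] + n_tot[:, None])
    terms = gammaln(alpha[None, :, :] + counts[:, None, :]) - gammaln(
        alpha[None, :, :]
    )
    return term0 + terms.sum(axis=2)


def _prior_logpmf(dvecs: np.ndarray, prior: np.ndarray, k: int) -> np.ndarray:
    """log multinomial(k, prior) pmf of each dosage vector (n_d,)."""
    prior = np.asarray(prior, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.where(prior > 0, np.log(np.maximum(prior, 1e-300)), -np.inf)
    lp = gammaln(k + 1) - gammaln(dvecs + 1).sum(axis=1)
    contrib = np.where(dvecs > 0, dvecs * logp[None, :], 0.0)
    return lp + contrib.sum(axis=1)


def _map_pick(post: np.ndarray, prior_lp: np.ndarray) -> np.ndarray:
    """Row-wise argmax with ties broken toward higher prior probability,
    then toward the lexicographically largest dosage vector (dosage
    vectors are pre-sorted lexicographically descending)."""
    n, n_d = post.shape
    best = post.max(axis=1, keepdims=True)
    tied = post >= best - 1e-9
    # among tied: maximise prior, then minimal index (lexicographically
    # largest vector given the descending sort)
    score = np.where(tied, prior_lp[None, :], -np.inf)
    best_prior = score.max(axis=1, keepdims=True)
    tied &= score >= best_prior - 1e-12
    return tied.argmax(axis=1)


def call_dosage(
    read_counts: Sequence[int] | np.ndarray,
    model: DosageModel | None = None,
    k: int = 4,
    prior: np.ndarray | None = None,
) -> np.ndarray | None:
    """MAP dosage vector for one individual at one locus.

    Returns ``None`` (missing) when total reads are zero.
    """
    model = model or DosageModel()
    counts = np.asarray(read_counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("negative read counts")
    if counts.sum() == 0:
        return None
    a = counts.shape[0]
    if prior is None:
        prior = np.full(a, 1.0 / a)
    dvecs = dosage_vectors(k, a)
    q = expected_proportions(dvecs, k, model.error_rate)
    ll = _read_loglik(counts[None, :], q, model.overdispersion)
    prior_lp = _prior_logpmf(dvecs, prior, k)
    post = ll + prior_lp[None, :]
    idx = _map_pick(post, prior_lp)
    return dvecs[idx[0]]


def _call_locus(
    counts: np.ndarray,
    model: DosageModel,
    k: int,
    priors: np.ndarray,
) -> list[np.ndarray | None]:
    """Vectorised MAP calls for one locus.

    counts: (n_samples, A); priors: (n_samples, A) per-sample prior
    frequency vectors (rows may repeat per population)."""
    n, a = counts.shape
    dvecs = dosage_vectors(k, a)
    q = expected_proportions(dvecs, k, model.error_rate)
    ll = _read_loglik(counts, q, model.overdispersion)
    out: list[np.ndarray | None] = [None] * n
    nonzero = counts.sum(axis=1) > 0
    # group rows by identical prior to share the prior term
    uniq, inverse = np.unique(priors, axis=0, return_inverse=True)
    for g in range(uniq.shape[0]):
        rows = np.where((inverse == g) & nonzero)[0]
        if rows.size == 0:
            continue
        prior_lp = _prior_logpmf(dvecs, uniq[g], k)
        post = ll[rows] + prior_lp[None, :]
        idx = _map_pick(post, prior_lp)
        for r, i in zip(rows, idx):
            out[r] = dvecs[i]
    return out


def _locus_layout(table: MADCTable) -> dict[str, list]:
    """Per locus: allele record list ordered Ref, Alt, then the rest in
    file order."""
    layout = {}
    for locus, recs in table.locus_index().items():
        ref = [r for r in recs if r.hap_class == "Ref"]
        alt = [r for r in recs if r.hap_class == "Alt"]
        rest = [r for r in recs if r.hap_class not in ("Ref", "Alt")]
        if not ref:
            raise ValueError(f"locus {locus} has no Ref record")
        layout[locus] = ref[:1] + alt[:1] + rest
    return layout


def iterate_frequency_prior(
    table: MADCTable,
    model: DosageModel | None = None,
    pops: PopulationAssignment | None = None,
    k: int = 4,
) -> GenotypeMatrix:
    """Call dosages for every sample x locus with iterated priors.

    Round one uses uniform allele frequencies; each further round
    recomputes per-population allele frequencies from the current calls
    (with a 0.5 pseudocount per allele so no observed allele is zeroed
    out) and re-calls with those as priors.  Deterministic given inputs.
    """
    model = model or DosageModel()
    layout = _locus_layout(table)
    loci = list(layout)
    samples = table.sample_ids
    n = len(samples)
    if pops is None:
        pop_of = np.zeros(n, dtype=int)
        n_pops = 1
    else:
        labels = pops.population_labels()
        lab_pos = {p: i for i, p in enumerate(labels)}
        pop_of = np.array([lab_pos[pops.population_of(s)] for s in samples])
        n_pops = len(labels)

    counts_by_locus = {
        locus: np.stack([r.counts for r in recs], axis=1)
        for locus, recs in layout.items()
    }

    calls: dict[str, list[np.ndarray | None]] = {}
    for it in range(max(1, model.n_prior_iterations)):
        for locus in loci:
            counts = counts_by_locus[locus]
            a = counts.shape[1]
            if it == 0:
                priors = np.full((n, a), 1.0 / a)
            else:
                prev = calls[locus]
                pf = np.full((n_pops, a), 1.0 / a)
                for p in range(n_pops):
                    tallies = np.zeros(a)
                    copies = 0
                    for s in np.where(pop_of == p)[0]:
                        d = prev[s]
                        if d is not None:
                            tallies += d
                            copies += k
                    if copies:
                        pf[p] = (tallies + 0.5) / (copies + 0.5 * a)
                priors = pf[pop_of]
            calls[locus] = _call_locus(counts, model, k, priors)

    allele_ids = {l: [r.allele_id for r in layout[l]] for l in loci}
    allele_seqs = {l: [r.sequence for r in layout[l]] for l in loci}
    call_rows = [[calls[l][s] for l in loci] for s in range(n)]
    return GenotypeMatrix(
        sample_ids=list(samples),
        locus_ids=loci,
        allele_ids=allele_ids,
        calls=call_rows,
        ploidy=k,
        allele_sequences=allele_seqs,
    )


def collapse_to_target_snp(
    table: MADCTable,
    model: DosageModel | None = None,
    pops: PopulationAssignment | None = None,
    k: int = 4,
) -> GenotypeMatrix:
    """Biallelic target-SNP dosages: only Ref and Alt read depths are
    used (RefMatch/AltMatch reads discarded); loci without an Alt record
    are called monomorphic (dosage ``k`` of the reference allele)."""
    core = [r for r in table.records if r.hap_class in ("Ref", "Alt")]
    reduced = MADCTable(table.sample_ids, core, table.n_missing_cells)
    return iterate_frequency_prior(reduced, model, pops, k)


def estimate_overdispersion(
    table: MADCTable,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    model: DosageModel | None = None,
    k: int = 4,
    min_depth: int = 30,
    min_cells: int = 50,
    max_cells: int = 2000,
) -> float:
    """Select the grid overdispersion maximising the summed
    Dirichlet-multinomial log-likelihood of high-depth count cells under
    provisional maximum-likelihood dosages.

    Falls back to ``rho = 0`` with a warning when fewer than
    ``min_cells`` sample x locus cells reach ``min_depth`` total reads.
    """
    model = model or DosageModel()
    layout = _locus_layout(table)
    cells: list[tuple[np.ndarray, int]] = []  # (counts, n_alleles)
    for locus, recs in layout.items():
        counts = np.stack([r.counts for r in recs], axis=1)
        tot = counts.sum(axis=1)
        for s in np.where(tot >= min_depth)[0]:
            cells.append(counts[s])
            if len(cells) >= max_cells:
                break
        if len(cells) >= max_cells:
            break
    if len(cells) < min_cells:
        warnings.warn(
            f"only {len(cells)} high-depth cells (<{min_cells}); "
            "falling back to overdispersion 0"
        )
        return 0.0

    # provisional ML dosage under the multinomial (rho = 0), flat prior
    by_a: dict[int, list[np.ndarray]] = {}
    for c in cells:
        by_a.setdefault(c.shape[0], []).append(c)
    total_ll = np.zeros(len(rho_grid))
    for a, cs in by_a.items():
        X = np.stack(cs)
        dvecs = dosage_vectors(k, a)
        q = expected_proportions(dvecs, k, model.error_rate)
        ml_idx = _read_loglik(X, q, 0.0).argmax(axis=1)
        for gi, rho in enumerate(rho_grid):
            ll = _read_loglik(X, q, rho)
            total_ll[gi] += ll[np.arange(X.shape[0]), ml_idx].sum()
    return float(rho_grid[int(np.argmax(total_ll))])
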