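"""Synthetic multi-population autotetraploid cohorts in MADC format.

The generative model is the multiallelic Balding-Nichols structure
model: each locus draws an ancestral allele-frequency vector ``pi`` from
a symmetric Dirichlet, and each population independently draws its own
frequency vector from ``Dirichlet(pi (1-F)/F)``, so that allele
frequencies diverge from the ancestral values with variance
``pi_a (1 - pi_a) F`` — ``F`` plays the role of the expected F_ST.
Individuals are tetrasomic Hardy-Weinberg: the dosage vector at each
locus is multinomial(ploidy, population frequencies); double reduction
is not simulated.  Sequencing is emulated with a negative-binomial total
depth per sample x locus (mean ~100x, matching amplicon panels) and
Dirichlet-multinomial allele counts around the error-adjusted expected
proportions of the true dosage.

Every draw flows from one seed: identical configs give byte-identical
MADC files.  The ``paper_like`` preset mirrors the cohort scale of the
alfalfa study this pipeline is designed around (28 populations x ~44
plants x 3,000 loci); ``small`` (4 x 40 x 500) keeps test runs fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import count

import numpy as np

from tetrahap.dosage import GenotypeMatrix, expected_proportions
from tetrahap.madc_io import (
    DEFAULT_ADAPTOR,
    HaplotypeRecord,
    MADCTable,
    PopulationAssignment,
    write_madc,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    n_pops: int = 4
    pop_size: int = 40
    n_loci: int = 500
    # Balding-Nichols F: one value for the whole cohort, or one per
    # population (heterogeneous drift)
    differentiation: float | tuple[float, ...] = 0.10
    min_alleles: int = 2
    max_alleles: int = 4
    dirichlet_concentration: float = 1.0  # ancestral frequency prior
    ploidy: int = 4
    depth_mean: float = 100.0
    depth_dispersion: float = 5.0  # negative-binomial size parameter
    error_rate: float = 0.001
    overdispersion: float = 0.0
    seq_length: int = 54
    adaptor: str = DEFAULT_ADAPTOR
    adaptor_fraction: float = 0.0  # fraction of records with 3' adaptor
    seed: int = 1

    def __post_init__(self) -> None:
        fs = self.pop_differentiation()
        if len(fs) != self.n_pops or any(not 0 < f < 1 for f in fs):
            raise ValueError(
                "differentiation F must be in (0, 1), scalar or one per population"
            )
        if self.min_alleles < 2 or self.max_alleles < self.min_alleles:
            raise ValueError("invalid allele range")
        if self.n_pops < 1 or self.pop_size < 1 or self.n_loci < 1:
            raise ValueError("sizes must be >= 1")

    def pop_differentiation(self) -> tuple[float, ...]:
        f = self.differentiation
        if np.isscalar(f):
            return (float(f),) * self.n_pops
        return tuple(float(x) for x in f)


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """The 4 x 40 x 500-locus test-scale cohort."""
    return replace(SimConfig(seed=seed), **overrides)


def paper_like_config(seed: int = 1, **overrides) -> SimConfig:
    """A 28-population, 44-plant, 3,000-locus cohort at ~100x depth."""
    return replace(
        SimConfig(n_pops=28, pop_size=44, n_loci=3000, seed=seed), **overrides
    )


@dataclass
class SimTruth:
    config: SimConfig
    locus_ids: list[str]
    n_alleles: np.ndarray  # per locus
    ancestral: list[np.ndarray]  # per locus frequency vector
    pop_freqs: list[np.ndarray]  # per locus (n_pops, A)
    pop_labels: list[str] = field(default_factory=list)
    dosages: list[list[np.ndarray]] | None = None  # [sample][locus]
    sample_ids: list[str] = field(default_factory=list)
    sample_pop: list[str] = field(default_factory=list)


def simulate_frequencies(cfg: SimConfig) -> SimTruth:
    """Draw ancestral and per-population allele frequencies."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    n_alleles = rng.integers(cfg.min_alleles, cfg.max_alleles + 1, cfg.n_loci)
    # synthetic coordinates: loci spread along 8 chromosomes
    locus_ids = []
    per_chrom = int(np.ceil(cfg.n_loci / 8))
    for i in range(cfg.n_loci):
        chrom = i // per_chrom + 1
        pos = (i % per_chrom) * 20_000 + 10_000
        locus_ids.append(f"chr{chrom}.1_{pos}")
    fs = cfg.pop_differentiation()
    ancestral, pop_freqs = [], []
    for li in range(cfg.n_loci):
        a = int(n_alleles[li])
        pi = rng.dirichlet(np.full(a, cfg.dirichlet_concentration))
        pi = np.maximum(pi, 1e-4)
        pi /= pi.sum()
        pf = np.stack(
            [rng.dirichlet(pi * (1 - f) / f) for f in fs]
        )
        ancestral.append(pi)
        pop_freqs.append(pf)
    labels = [f"POP{p + 1:02d}" for p in range(cfg.n_pops)]
    return SimTruth(cfg, locus_ids, n_alleles, ancestral, pop_freqs, labels)


def simulate_genotypes(truth: SimTruth, cfg: SimConfig | None = None) -> SimTruth:
    """Draw multinomial(ploidy, pop frequency) dosage vectors for every
    individual; fills the truth record in place and returns it."""
    cfg = cfg or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 22]))
    sample_ids, sample_pop = [], []
    for p, lab in enumerate(truth.pop_labels):
        for i in range(cfg.pop_size):
            sample_ids.append(f"{lab}_ind{i + 1:03d}")
            sample_pop.append(lab)
    dosages: list[list[np.ndarray]] = [[] for _ in sample_ids]
    for li in range(cfg.n_loci):
        pf = truth.pop_freqs[li]
        for p in range(len(truth.pop_labels)):
            block = rng.multinomial(cfg.ploidy, pf[p], size=cfg.pop_size)
            for i in range(cfg.pop_size):
                dosages[p * cfg.pop_size + i].append(block[i])
    truth.dosages = dosages
    truth.sample_ids = sample_ids
    truth.sample_pop = sample_pop
    return truth


def _locus_sequences(
    rng: np.random.Generator, a: int, length: int
) -> list[str]:
    """Reference sequence plus a - 1 variants each differing by >= 1 SNP."""
    ref = rng.choice(_BASES, size=length)
    seqs = ["".join(ref)]
    used = {seqs[0]}
    pos_iter = count(0)
    while len(seqs) < a:
        pos = next(pos_iter) % length
        var = ref.copy()
        alternatives = [b for b in "ACGT" if b != ref[pos]]
        var[pos] = rng.choice(alternatives)
        # later alleles also vary a second (off-target) site
        if len(seqs) >= 2:
            pos2 = (pos + length // 2) % length
            alts2 = [b for b in "ACGT" if b != ref[pos2]]
            var[pos2] = rng.choice(alts2)
        s = "".join(var)
        if s not in used:
            used.add(s)
            seqs.append(s)
    return seqs


def simulate_reads(truth: SimTruth, cfg: SimConfig | None = None) -> MADCTable:
    """Emit overdispersed read counts for every sample x locus as an
    MADC table (alleles labeled Ref, Alt, AltMatch_01, ...)."""
    cfg = cfg or truth.config
    if truth.dosages is None:
        raise ValueError("simulate_genotypes must run first")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 33]))
    n = len(truth.sample_ids)
    records: list[HaplotypeRecord] = []
    nb_p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    for li, locus in enumerate(truth.locus_ids):
        a = int(truth.n_alleles[li])
        seqs = _locus_sequences(rng, a, cfg.seq_length)
        depth = rng.negative_binomial(cfg.depth_dispersion, nb_p, size=n)
        counts = np.zeros((n, a), dtype=np.int64)
        for s in range(n):
            if depth[s] == 0:
                continue
            d = truth.dosages[s][li]
            q = expected_proportions(d, cfg.ploidy, cfg.error_rate)[0]
            if cfg.overdispersion > 0:
                rho = cfg.overdispersion
                q = rng.dirichlet(q * (1 - rho) / rho)
            counts[s] = rng.multinomial(depth[s], q)
        suffixes = ["Ref", "Alt"] + [
            f"AltMatch_{j:02d}" for j in range(1, max(a - 2, 0) + 1)
        ]
        for ai in range(a):
            seq = seqs[ai]
            if cfg.adaptor_fraction > 0 and rng.random() < cfg.adaptor_fraction:
                seq = seq + cfg.adaptor
            records.append(
                HaplotypeRecord(
                    locus_id=locus,
                    allele_id=f"{locus}|{suffixes[ai]}",
                    hap_class=suffixes[ai].split("_")[0],
                    sequence=seq,
                    counts=counts[:, ai],
                )
            )
    return MADCTable(list(truth.sample_ids), records)


def population_assignment(truth: SimTruth) -> PopulationAssignment:
    return PopulationAssignment(
        dict(zip(truth.sample_ids, truth.sample_pop))
    )


def truth_genotypes(truth: SimTruth) -> GenotypeMatrix:
    """The simulated dosages as a GenotypeMatrix (the recovery target)."""
    if truth.dosages is None:
        raise ValueError("simulate_genotypes must run first")
    allele_ids = {}
    for li, locus in enumerate(truth.locus_ids):
        a = int(truth.n_alleles[li])
        suffixes = ["Ref", "Alt"] + [
            f"AltMatch_{j:02d}" for j in range(1, max(a - 2, 0) + 1)
        ]
        allele_ids[locus] = [f"{locus}|{s}" for s in suffixes[:a]]
    calls = [
        [np.asarray(truth.dosages[s][li]) for li in range(len(truth.locus_ids))]
        for s in range(len(truth.sample_ids))
    ]
    return GenotypeMatrix(
        sample_ids=list(truth.sample_ids),
        locus_ids=list(truth.locus_ids),
        allele_ids=allele_ids,
        calls=calls,
        ploidy=truth.config.ploidy,
    )


def oracle_fst(truth: SimTruth) -> "np.ndarray":
    """Pairwise F_ST computed directly from the realized true population
    frequencies (ratio of sums across loci); (n_pops, n_pops)."""
    P = len(truth.pop_labels)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            num = den = 0.0
            for li in range(len(truth.locus_ids)):
                pi_ = truth.pop_freqs[li][i]
                pj_ = truth.pop_freqs[li][j]
                hs = 1 - 0.5 * (np.sum(pi_**2) + np.sum(pj_**2))
                pbar = 0.5 * (pi_ + pj_)
                ht = 1 - np.sum(pbar**2)
                num += ht - hs
                den += ht
            v = num / den if den > 0 else np.nan
            out[i, j] = out[j, i] = max(v, 0.0)
    return out


def simulate_cohort(cfg: SimConfig) -> tuple[MADCTable, PopulationAssignment, SimTruth]:
    """Frequencies -> genotypes -> reads in one call."""
    truth = simulate_frequencies(cfg)
    simulate_genotypes(truth, cfg)
    table = simulate_reads(truth, cfg)
    return table, population_assignment(truth), truth


def write_cohort(cfg: SimConfig, out_dir) -> dict[str, str]:
    """Write madc.csv, pops.tsv and truth-summary files to ``out_dir``."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, pops, truth = simulate_cohort(cfg)
    write_madc(table, out / "madc.csv")
    pops.to_tsv(out / "pops.tsv")
    summary = {
        "seed": cfg.seed,
        "n_pops": cfg.n_pops,
        "pop_size": cfg.pop_size,
        "n_loci": cfg.n_loci,
        "differentiation": cfg.differentiation,
        "mean_oracle_fst": float(
            oracle_fst(truth)[np.triu_indices(cfg.n_pops, 1)].mean()
        ),
    }
    (out / "truth.json").write_text(json.dumps(summary, indent=2))
    return {k: str(out / v) for k, v in
            {"madc": "madc.csv", "pops": "pops.tsv", "truth": "truth.json"}.items()}
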