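"""Intra-population diversity statistics for polyploid genotype matrices.

Definitions (per population, averaged over loci unless stated):

* ``H_O`` — observed heterozygosity of an autotetraploid individual is
  its within-individual gene diversity: the probability that two allele
  copies drawn without replacement differ, ``1 - sum_a C(d_a,2)/C(k,2)``.
* ``H_S`` — small-sample-corrected gene diversity
  ``(c/(c-1)) (1 - sum_a p_a^2)`` with ``c`` the number of allele copies
  sampled (``k`` x non-missing individuals).
* ``N_E`` — effective allele number, computed per locus as
  ``1/(1 - H_S,l)`` and then averaged over loci (not the pooled
  ``1/(1-mean H_S)``, which Jensen's inequality makes systematically
  smaller).
* ``F_IS = 1 - mean(H_O)/mean(H_S)`` (ratio of means, so monomorphic
  loci — which contribute zero to both — do not destabilise it).
* ``PIC`` — Botstein's polymorphism information content.
* ``H_T`` — gene diversity of the unweighted mean across-population
  allele frequencies (populations weighted equally).

Monomorphic loci are included in the H_O/H_S/PIC means (contributing 0);
the monomorphic percentage is tabulated separately.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from tetrahap.dosage import GenotypeMatrix
from tetrahap.madc_io import PopulationAssignment


def individual_heterozygosity(dosage, k: int = 4) -> float:
    """Probability that two allele copies of one individual differ."""
    d = np.asarray(dosage)
    if d.sum() != k or np.any(d < 0):
        raise ValueError(f"invalid dosage vector {d} for ploidy {k}")
    pairs_same = (d * (d - 1) / 2).sum()
    return float(1 - pairs_same / (k * (k - 1) / 2))


def gene_diversity(freqs, c: int | None = None) -> float:
    """Small-sample-corrected expected heterozygosity of one locus.

    ``c`` is the allele-copy sample size; ``c=None`` gives the
    uncorrected ``1 - sum p^2``.
    """
    p = np.asarray(freqs, dtype=float)
    h = 1.0 - float(np.sum(p**2))
    if c is None:
        return h
    if c < 2:
        raise ValueError("allele-copy count must be >= 2 for the correction")
    return c / (c - 1) * h


def effective_alleles(h_values, cap: float = 1e6) -> float:
    """Mean over loci of the per-locus effective allele number
    ``1/(1 - H_l)``; loci with ``H = 1`` are capped with a warning."""
    h = np.asarray(h_values, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("H values must be in [0, 1]")
    ne = np.empty_like(h)
    sat = h >= 1 - 1 / cap
    if np.any(sat):
        warnings.warn("locus with H ~= 1 capped in effective allele number")
    ne[sat] = cap
    ne[~sat] = 1.0 / (1.0 - h[~sat])
    return float(ne.mean())


def pic(freqs) -> float:
    """Botstein polymorphism information content:
    ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``."""
    p = np.asarray(freqs, dtype=float)
    s2 = np.sum(p**2)
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = s2**2 - np.sum(p**4)
    return float(1 - s2 - cross)


def allele_frequencies(
    genotypes: GenotypeMatrix, pops: PopulationAssignment
) -> dict[str, dict[str, tuple[np.ndarray, int]]]:
    """Per population x locus: (frequency vector over the locus's allele
    list, allele-copy sample size c = k x non-missing individuals).

    Cells with no typed individuals are omitted.
    """
    k = genotypes.ploidy
    sample_pop = [pops.population_of(s) for s in genotypes.sample_ids]
    labels = pops.population_labels()
    out: dict[str, dict[str, tuple[np.ndarray, int]]] = {p: {} for p in labels}
    for locus in genotypes.locus_ids:
        dt = genotypes.dosage_tensor(locus)
        for p in labels:
            rows = [i for i, sp in enumerate(sample_pop) if sp == p]
            sub = dt[rows]
            ok = ~np.isnan(sub[:, 0])
            n_called = int(ok.sum())
            if n_called == 0:
                continue
            tallies = sub[ok].sum(axis=0)
            out[p][locus] = (tallies / tallies.sum(), k * n_called)
    return out


def _pop_locus_stats(
    genotypes: GenotypeMatrix, sample_rows: list[int]
) -> pd.DataFrame:
    """Per-locus Num/H_O/H_S/PIC/N_E for one set of individuals."""
    k = genotypes.ploidy
    rows = []
    for li, locus in enumerate(genotypes.locus_ids):
        tallies = np.zeros(len(genotypes.allele_ids[locus]))
        ho_sum, n_called = 0.0, 0
        for s in sample_rows:
            d = genotypes.calls[s][li]
            if d is None:
                continue
            tallies += d
            ho_sum += 1 - (d * (d - 1) / 2).sum() / (k * (k - 1) / 2)
            n_called += 1
        if n_called == 0:
            continue
        c = k * n_called
        p = tallies / tallies.sum()
        n_obs = int(np.sum(tallies > 0))
        hs = gene_diversity(p, c) if c >= 2 else np.nan
        rows.append(
            {
                "locus": locus,
                "num": n_obs,
                "h_o": ho_sum / n_called,
                "h_s": hs,
                "pic": pic(p),
                "mono": n_obs <= 1,
            }
        )
    return pd.DataFrame(rows)


def diversity_table(
    genotypes: GenotypeMatrix,
    pops: PopulationAssignment,
    include_total: bool = True,
) -> pd.DataFrame:
    """Per-population diversity summary plus global ``H_T``.

    Columns: ``population, size, mon_pct, num, n_e, h_o, h_s, f_is,
    pic``; an extra ``TOTAL`` row pools all samples, and ``h_t`` is
    attached as a DataFrame attribute ``df.attrs["h_t"]``.
    """
    sample_pop = [pops.population_of(s) for s in genotypes.sample_ids]
    labels = pops.population_labels()
    out_rows = []
    groups: dict[str, list[int]] = {
        p: [i for i, sp in enumerate(sample_pop) if sp == p] for p in labels
    }
    for p, rows in list(groups.items()):
        if len(rows) < 2:
            warnings.warn(f"population {p} has <2 individuals; excluded")
            del groups[p]
    entries = list(groups.items())
    if include_total:
        entries.append(("TOTAL", list(range(len(genotypes.sample_ids)))))
    for p, rows in entries:
        st = _pop_locus_stats(genotypes, rows)
        if st.empty:
            continue
        mean_ho = st["h_o"].mean()
        mean_hs = st["h_s"].mean()
        poly = st[~st["mono"]]
        if poly.empty or poly["h_s"].sum() <= 0:
            f_is = np.nan
        else:
            f_is = 1 - poly["h_o"].sum() / poly["h_s"].sum()
        out_rows.append(
            {
                "population": p,
                "size": len(rows),
                "mon_pct": 100.0 * st["mono"].mean(),
                "num": st["num"].mean(),
                "n_e": effective_alleles(st["h_s"].clip(0, 1)),
                "h_o": mean_ho,
                "h_s": mean_hs,
                "f_is": f_is,
                "pic": st["pic"].mean(),
            }
        )
    df = pd.DataFrame(out_rows)

    # H_T: gene diversity of unweighted mean across-population frequencies
    freqs = allele_frequencies(genotypes, pops)
    ht_per_locus = []
    for locus in genotypes.locus_ids:
        vecs = [freqs[p][locus][0] for p in groups if locus in freqs[p]]
        if not vecs:
            continue
        pbar = np.mean(vecs, axis=0)
        ht_per_locus.append(gene_diversity(pbar))
    df.attrs["h_t"] = float(np.mean(ht_per_locus)) if ht_per_locus else np.nan
    return df
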