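"""End-to-end orchestration: filter -> dose -> diversity ->
differentiation -> structure -> LD, from a single config.

All outputs are plain TSV/VCF/newick/JSON files; reruns with the same
config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tetrahap.differentiation import (
    amova,
    locus_fst,
    nj_tree,
    pairwise_differentiation,
    private_alleles,
)
from tetrahap.diversity import allele_frequencies, diversity_table
from tetrahap.dosage import (
    DosageModel,
    collapse_to_target_snp,
    estimate_overdispersion,
    iterate_frequency_prior,
)
from tetrahap.haplotype_filter import FilterConfig, apply_filters
from tetrahap.madc_io import (
    PopulationAssignment,
    parse_locus_coordinate,
    parse_madc,
    write_madc,
    write_vcf,
)
from tetrahap.structure_ld import fit_ld_decay, ld_pairs, pca

log = logging.getLogger("tetrahap")


@dataclass
class RunConfig:
    madc_path: str
    pops_path: str
    out_dir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    dosage: DosageModel = field(default_factory=DosageModel)
    ploidy: int = 4
    estimate_rho: bool = True
    n_permutations: int = 1000
    ld_max_distance: int = 1_000_000
    ld_maf_min: float = 0.05
    ld_threshold: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for p in (self.madc_path, self.pops_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _manifest(cfg: RunConfig, extra: dict) -> dict:
    payload = json.dumps(
        {**{k: str(v) for k, v in asdict(cfg).items()}},
        sort_keys=True,
    )
    from tetrahap import __version__ as version

    return {
        "tetrahap_version": version,
        "seed": cfg.seed,
        "parameter_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        **extra,
    }


def run_all(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a dict of artifact paths plus the
    in-memory results most callers want (diversity tables, matrices)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pops = PopulationAssignment.from_tsv(cfg.pops_path)

    log.info("parsing MADC %s", cfg.madc_path)
    table = parse_madc(cfg.madc_path)
    filtered, report = apply_filters(table, cfg.filter)
    write_madc(filtered, out / "filtered_madc.csv")
    report.to_tsv(out / "filter_report.tsv")
    log.info(
        "filtered: %d loci, %d samples, %d haplotypes retained",
        report.loci_retained, report.samples_retained, report.haps_retained,
    )

    kept = set(filtered.sample_ids)
    pops = PopulationAssignment(
        {s: p for s, p in pops.populations.items() if s in kept}, pops.groups
    )

    model = cfg.dosage
    if cfg.estimate_rho:
        rho_hat = estimate_overdispersion(filtered, model=model, k=cfg.ploidy)
        model = DosageModel(model.error_rate, rho_hat, model.n_prior_iterations)
        log.info("estimated overdispersion rho = %.3f", rho_hat)

    geno_mh = iterate_frequency_prior(filtered, model, pops, cfg.ploidy)
    geno_snp = collapse_to_target_snp(filtered, model, pops, cfg.ploidy)
    coords = {l: parse_locus_coordinate(l) for l in geno_mh.locus_ids}
    write_vcf(geno_mh, coords, out / "microhap.vcf")
    write_vcf(geno_snp, coords, out / "target_snp.vcf")

    results: dict = {"paths": {}, "report": report}
    for mode, geno in (("microhap", geno_mh), ("snp", geno_snp)):
        div = diversity_table(geno, pops)
        div.to_csv(out / f"diversity_{mode}.tsv", sep="\t", index=False)
        results[f"diversity_{mode}"] = div
        for stat in ("fst", "rho"):
            m = pairwise_differentiation(geno, pops, stat)
            m.to_dataframe().to_csv(out / f"pairwise_{stat}_{mode}.tsv", sep="\t")
            results[f"{stat}_{mode}"] = m
    locus_fst(geno_mh, pops).to_csv(out / "locus_fst.tsv", sep="\t", index=False)
    freqs = allele_frequencies(geno_mh, pops)
    private_alleles(freqs, geno_mh.allele_ids).to_csv(
        out / "private_alleles.tsv", sep="\t", index=False
    )

    am = amova(geno_mh, pops, cfg.n_permutations, cfg.seed)
    am.to_csv(out / "amova.tsv", sep="\t", index=False)
    results["amova"] = am
    if len(pops.population_labels()) >= 3:
        (out / "nj_rho.nwk").write_text(nj_tree(results["rho_microhap"]) + "\n")

    dos = geno_snp.alt_dosage_matrix()
    var_cols = np.nanstd(dos, axis=0) > 0
    if var_cols.sum() >= 2:
        p = pca(np.nan_to_num(dos[:, var_cols]))
        pd.DataFrame(
            {"component": np.arange(1, 11), "pct_var": p.percent_variance[:10]}
        ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        results["pca"] = p

    coord_list = [coords[l] for l in geno_snp.locus_ids]
    pairs = ld_pairs(dos, coord_list, cfg.ld_maf_min, cfg.ld_max_distance)
    pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
    if len(pairs) >= 100:
        fit = fit_ld_decay(pairs, len(geno_snp.sample_ids), cfg.ld_threshold)
        pd.DataFrame(
            [{
                "a": fit.a,
                "n": fit.n,
                "threshold": fit.threshold,
                "decay_distance_kb": fit.decay_distance_bp / 1000,
                "n_pairs": fit.n_pairs,
            }]
        ).to_csv(out / "ld_fit.tsv", sep="\t", index=False)
        results["ld_fit"] = fit

    manifest = _manifest(cfg, {
        "loci_retained": report.loci_retained,
        "samples_retained": report.samples_retained,
        "overdispersion": model.overdispersion,
    })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    results["paths"] = {p.name: str(p) for p in out.iterdir()}
    return results
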