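"""Reading and writing MADC (Missing Allele Discovery Count) files.

An MADC file carries, for every amplicon locus, the per-sample read depth
of each distinct microhaplotype sequence observed at that locus.  The
haplotype classes follow the DArTag convention: ``Ref`` and ``Alt`` carry
the reference/alternative base at the designed target SNP and no other
variant; ``RefMatch``/``AltMatch`` additionally carry off-target SNPs;
anything else is ``Other``.

Dialect (written by :mod:`tetrahap.synthetic_data` and accepted here):
CSV with columns ``AlleleID, CloneID, AlleleSequence, <sample...>`` where
``AlleleID = <locus_id>|<suffix>`` and the suffix is ``Ref``, ``Alt``,
``RefMatch_NN``, ``AltMatch_NN`` or ``Other_NN``.  Real DArT exports with
different column names can be read by passing a column map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HAP_CLASSES = ("Ref", "Alt", "RefMatch", "AltMatch", "Other")

#: adaptor that DArTag leaves on amplicons longer than the 54-bp core
DEFAULT_ADAPTOR = "ACCGATCTCGTATGCCGTCTTCTGCTTG"

_DNA_RE = re.compile(r"^[ACGT]+$")


@dataclass
class HaplotypeRecord:
    """One microhaplotype at one locus with per-sample read depths."""

    locus_id: str
    allele_id: str
    hap_class: str
    sequence: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.hap_class not in HAP_CLASSES:
            raise ValueError(f"unknown haplotype class {self.hap_class!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError(f"negative read count in {self.allele_id}")


@dataclass
class MADCTable:
    """An in-memory MADC file: sample roster plus haplotype records."""

    sample_ids: list[str]
    records: list[HaplotypeRecord]
    n_missing_cells: int = 0

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        n = len(self.sample_ids)
        for rec in self.records:
            if rec.counts.shape != (n,):
                raise ValueError(
                    f"{rec.allele_id}: counts length {rec.counts.shape[0]} "
                    f"!= roster size {n}"
                )

    @property
    def locus_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.locus_id, None)
        return list(seen)

    def locus_index(self) -> dict[str, list[HaplotypeRecord]]:
        idx: dict[str, list[HaplotypeRecord]] = {}
        for rec in self.records:
            idx.setdefault(rec.locus_id, []).append(rec)
        return idx

    def locus_depth(self) -> pd.DataFrame:
        """Total read depth per locus (rows) x sample (columns)."""
        loci = self.locus_ids
        depth = np.zeros((len(loci), len(self.sample_ids)), dtype=np.int64)
        pos = {l: i for i, l in enumerate(loci)}
        for rec in self.records:
            depth[pos[rec.locus_id]] += rec.counts
        return pd.DataFrame(depth, index=loci, columns=self.sample_ids)

    def subset_samples(self, keep: Sequence[str]) -> "MADCTable":
        order = [self.sample_ids.index(s) for s in keep]
        recs = [
            HaplotypeRecord(
                r.locus_id, r.allele_id, r.hap_class, r.sequence, r.counts[order]
            )
            for r in self.records
        ]
        return MADCTable(list(keep), recs, self.n_missing_cells)


@dataclass(frozen=True)
class LocusCoordinate:
    """1-based physical position of a locus on a chromosome."""

    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("empty chromosome token")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")


@dataclass
class PopulationAssignment:
    """sample -> population mapping, optionally population -> group."""

    populations: dict[str, str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("no samples assigned")

    def population_of(self, sample_id: str) -> str:
        return self.populations[sample_id]

    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.populations.items() if p == population]

    @classmethod
    def from_tsv(cls, path) -> "PopulationAssignment":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns)
        pops = dict(zip(df[cols[0]], df[cols[1]]))
        groups = {}
        if len(cols) >= 3:
            sub = df.drop_duplicates(cols[1])
            groups = dict(zip(sub[cols[1]], sub[cols[2]].fillna("")))
        return cls(pops, groups)

    def to_tsv(self, path) -> None:
        rows = [
            {"sample_id": s, "population": p, "group": self.groups.get(p, "")}
            for s, p in self.populations.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class MADCFormatError(ValueError):
    pass


_SUFFIX_RE = re.compile(r"^(Ref|Alt|RefMatch|AltMatch|Other)(?:_\d+)?$")


def classify_allele_id(allele_id: str) -> tuple[str, str]:
    """Split ``locus|suffix`` into (locus_id, haplotype class)."""
    locus_id, sep, suffix = allele_id.rpartition("|")
    if not sep:
        raise MADCFormatError(f"AlleleID {allele_id!r} lacks '|' separator")
    m = _SUFFIX_RE.match(suffix)
    if not m:
        raise MADCFormatError(f"AlleleID {allele_id!r}: unknown suffix {suffix!r}")
    return locus_id, m.group(1)


def parse_madc(
    path,
    column_map: Mapping[str, str] | None = None,
) -> MADCTable:
    """Read an MADC CSV into an :class:`MADCTable`.

    Parameters
    ----------
    path
        CSV with header ``AlleleID, CloneID, AlleleSequence, <samples...>``.
    column_map
        Optional mapping from the dialect's canonical column names
        (``AlleleID``, ``AlleleSequence``) to the names used in the file,
        for real DArT exports with different headers.

    Missing count cells (empty or ``NA``) are read as depth 0 and counted
    in ``MADCTable.n_missing_cells`` — depth absence, not genotype
    missingness, which is decided downstream by the locus read filter.
    """
    cmap = {"AlleleID": "AlleleID", "AlleleSequence": "AlleleSequence"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str)
    for canonical, actual in cmap.items():
        if actual not in df.columns:
            raise MADCFormatError(f"missing required column {actual!r}")
    meta_cols = {cmap["AlleleID"], cmap["AlleleSequence"], "CloneID"}
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise MADCFormatError("no sample columns found")

    counts = df[sample_cols]
    n_missing = int(counts.isna().sum().sum() + (counts == "NA").sum().sum())
    counts = counts.replace("NA", "0").fillna("0")
    try:
        mat = counts.astype(np.int64).to_numpy()
    except ValueError as exc:
        bad = counts[~counts.apply(lambda s: s.str.fullmatch(r"-?\d+").fillna(False)).all(axis=1)]
        line = int(bad.index[0]) + 2 if len(bad) else -1
        raise MADCFormatError(f"non-integer count near line {line}: {exc}") from exc
    if np.any(mat < 0):
        line = int(np.argwhere((mat < 0).any(axis=1))[0][0]) + 2
        raise MADCFormatError(f"negative count at line {line}")

    allele_ids = df[cmap["AlleleID"]].astype(str).to_numpy()
    seqs = df[cmap["AlleleSequence"]].astype(str).to_numpy()
    records = []
    for i in range(len(df)):
        locus_id, hap_class = classify_allele_id(allele_ids[i])
        records.append(
            HaplotypeRecord(locus_id, allele_ids[i], hap_class, seqs[i], mat[i])
        )
    return MADCTable(sample_cols, records, n_missing)


def write_madc(table: MADCTable, path) -> None:
    """Write an :class:`MADCTable` back to the CSV dialect."""
    rows = []
    for rec in table.records:
        row = {
            "AlleleID": rec.allele_id,
            "CloneID": rec.locus_id,
            "AlleleSequence": rec.sequence,
        }
        row.update(dict(zip(table.sample_ids, rec.counts.tolist())))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def trim_adaptor(
    sequence: str, adaptor: str = DEFAULT_ADAPTOR, min_overlap: int = 10
) -> str:
    """Remove the adaptor (or a >= ``min_overlap`` prefix of it) from the
    3' end of ``sequence``; exact matching only.

    Returns the input unchanged when no 3'-terminal match is found.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not _DNA_RE.match(sequence) or not _DNA_RE.match(adaptor):
        raise ValueError("sequences must be over A/C/G/T")
    # longest adaptor prefix that is a suffix of the read wins
    for take in range(len(adaptor), min_overlap - 1, -1):
        if sequence.endswith(adaptor[:take]):
            return sequence[:-take]
    return sequence


def parse_locus_coordinate(locus_id: str) -> LocusCoordinate:
    """Parse ``<chrom>_<pos>`` locus names, e.g. ``chr8.1_62885594``.

    The chromosome token is everything before the final underscore, so
    names like ``scaffold_12_345`` parse as (``scaffold_12``, 345).
    """
    chrom, sep, tail = locus_id.rpartition("_")
    if not sep or not tail.isdigit():
        raise ValueError(f"locus id {locus_id!r} has no trailing _<integer>")
    return LocusCoordinate(chrom, int(tail))


def write_vcf(
    genotypes,
    coords: Mapping[str, LocusCoordinate],
    path,
    reference_name: str = "unknown",
) -> None:
    """Write a :class:`~tetrahap.dosage.GenotypeMatrix` as multiallelic
    VCF 4.3, one row per locus.

    Genotypes are unphased tetraploid calls (``0/0/1/1`` style, allele
    indices sorted ascending) plus an ``AD``-like ``DS`` FORMAT field
    carrying the per-allele dosage vector.  Loci are sorted by coordinate.
    """
    loci = list(genotypes.locus_ids)
    missing = [l for l in loci if l not in coords]
    if missing:
        raise ValueError(f"no coordinate for loci: {missing[:3]}...")
    order = sorted(range(len(loci)), key=lambda i: (coords[loci[i]].chromosome, coords[loci[i]].position))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write(f"##source=tetrahap\n##reference={reference_name}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=R,Type=Integer,Description="Allele dosage">\n')
        chroms = []
        for l in loci:
            c = coords[l].chromosome
            if c not in chroms:
                chroms.append(c)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for i in order:
            locus = loci[i]
            alleles = genotypes.allele_ids[locus]
            seqs = genotypes.allele_sequences.get(locus) if genotypes.allele_sequences else None
            if seqs:
                ref, alts = seqs[0], seqs[1:]
            else:
                # symbolic single-base placeholders when sequences are unknown
                ref = "N"
                alts = [f"<ALT{j}>" for j in range(1, len(alleles))]
            alt_field = ",".join(alts) if alts else "."
            co = coords[locus]
            fields = [
                co.chromosome,
                str(co.position),
                locus,
                ref,
                alt_field,
                ".",
                ".",
                ".",
                "GT:DS",
            ]
            for s in range(len(genotypes.sample_ids)):
                d = genotypes.calls[s][i]
                if d is None:
                    fields.append("./././.:" + ",".join(["."] * len(alleles)))
                else:
                    gt = "/".join(
                        str(a) for a in sorted(
                            idx for idx, c in enumerate(d) for _ in range(c)
                        )
                    )
                    fields.append(gt + ":" + ",".join(str(int(c)) for c in d))
            fh.write("\t".join(fields) + "\n")
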