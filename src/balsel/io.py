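"""Readers, writers, run configuration and the deterministic fixture generator.

The input convention: a VCF (v4.x) of biallelic SNPs, a sample-to-population
map (TSV: sample, population), and a per-site annotation table (TSV keyed by
chrom, pos, ref, alt with columns func_class, gene_id and optionally
recomb_rate and comma-separated gene_sets).  Per-population alternate-allele
frequencies are computed from genotypes (allele count over called alleles;
missing genotypes reduce the denominator).  Indels, multi-nucleotide
polymorphisms and multiallelic records are dropped at read time with
per-reason counts.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import PolymorphismCounts
from .model import BalancingSelectionResults
from .sites import BinnedCounts, SiteRecord

__all__ = [
    "RunConfig",
    "FixtureSpec",
    "read_sites",
    "read_population_map",
    "read_gene_counts",
    "generate_fixture",
    "write_results",
    "write_binned_counts",
    "read_binned_counts",
]

logger = logging.getLogger(__name__)

_SNP_ALLELES = {"A", "C", "G", "T"}


@dataclass
class RunConfig:
    """End-to-end run settings; the seed is recorded in every output manifest."""

    vcf_path: str | None = None
    pop_map_path: str | None = None
    annotation_path: str | None = None
    pop1: str = "pop1"
    pop2: str = "pop2"
    focal: str = "pop1"
    bin_width: float = 0.1
    min_bin_count: int = 20
    min_set_count: int = 100
    bootstrap_replicates: int = 100
    bootstrap_level: float = 0.95
    seed: int = 0
    out_dir: str = "results"
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_bin_count < 0 or self.min_set_count < 0:
            raise ValueError("count thresholds must be >= 0")


def read_population_map(path: str | Path) -> dict[str, str]:
    """Sample -> population from a two-column TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"sample", "population"} <= set(df.columns):
        pairs = df[["sample", "population"]].itertuples(index=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        pairs = df.iloc[:, :2].itertuples(index=False)
    return {s: p for s, p in pairs}


def _read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "func_class", "gene_id"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns: {sorted(missing)}")
    return ann.set_index(["chrom", "pos", "ref", "alt"])


def read_sites(
    vcf_path: str | Path,
    pop_map_path: str | Path,
    annotation_path: str | Path,
    strict: bool = False,
) -> list[SiteRecord]:
    """Read biallelic SNPs with per-population frequencies and annotations.

    Records that are not single-nucleotide biallelic SNPs, or that lack an
    annotation, are dropped (or raise, in strict mode); per-reason drop counts
    are logged.
    """
    from cyvcf2 import VCF

    pop_of = read_population_map(pop_map_path)
    ann = _read_annotation(annotation_path)
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    pops = sorted(set(pop_of.values()))
    pop_cols = {p: np.array([pop_of.get(s) == p for s in samples]) for p in pops}

    drops: Counter[str] = Counter()
    out: list[SiteRecord] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            drops["multiallelic"] += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            drops["not_snp"] += 1
            continue
        key = (str(rec.CHROM), int(rec.POS), ref, alt)
        try:
            meta = ann.loc[key]
        except KeyError:
            drops["unannotated"] += 1
            if strict:
                raise ValueError(f"no annotation for site {key}")
            continue
        if isinstance(meta, pd.DataFrame):
            meta = meta.iloc[0]
        # genotype array: columns 0,1 are alleles (-1 = missing)
        gts = rec.genotype.array()[:, :2]
        freqs: dict[str, float] = {}
        ok = True
        for p in pops:
            sub = gts[pop_cols[p]]
            called = sub >= 0
            denom = int(called.sum())
            if denom == 0:
                ok = False
                break
            freqs[p] = float((sub[called] == 1).sum() / denom)
        if not ok:
            drops["no_called_genotypes"] += 1
            continue
        recomb = meta.get("recomb_rate")
        gene_sets = meta.get("gene_sets")
        out.append(
            SiteRecord(
                chrom=key[0],
                pos=key[1],
                ref_allele=ref,
                alt_allele=alt,
                freq_by_pop=freqs,
                func_class=str(meta["func_class"]),
                gene_id=str(meta["gene_id"]),
                recomb_rate=None if pd.isna(recomb) else float(recomb),
                gene_sets=(
                    frozenset(str(gene_sets).split(","))
                    if isinstance(gene_sets, str) and gene_sets
                    else frozenset()
                ),
            )
        )
    if drops:
        logger.info("dropped records: %s", dict(drops))
    if not out:
        logger.warning("no usable SNPs read from %s", vcf_path)
    return out


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    """Per-gene count TSV with columns gene_id, s_n, s_s, r_n, r_s."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "s_n", "s_s", "r_n", "r_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene count file lacks columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# fixture generation


@dataclass
class FixtureSpec:
    """Target composition for a synthetic two-population SNP fixture.

    ``targets`` maps a folded-MAF bin index (0-4, bins of width 0.1) to the
    (s_n, s_s, r_n, r_s) table that bin must reproduce after the full
    classify-bin-count pipeline.  Frequencies are placed at the bin midpoint,
    snapped to the genotype grid of ``n_samples`` diploids per population.
    """

    targets: Mapping[int, tuple[int, int, int, int]]
    n_genes: int = 10
    n_samples: int = 50
    pop1: str = "pop1"
    pop2: str = "pop2"
    seed: int = 0
    shared_other_freq: float = 0.3

    def __post_init__(self) -> None:
        for b, t in self.targets.items():
            if not 0 <= b <= 4:
                raise ValueError(f"bin index {b} out of range 0-4")
            if any(c < 0 for c in t):
                raise ValueError("target counts must be non-negative")
        if self.n_genes < 1 or self.n_samples < 5:
            raise ValueError("need at least 1 gene and 5 samples per population")


def _genotype_column(k_alt: int, n_samples: int) -> list[str]:
    """Genotypes realizing exactly k_alt alternate alleles among 2*n_samples."""
    gts = ["1/1"] * (k_alt // 2)
    if k_alt % 2:
        gts.append("0/1")
    gts += ["0/0"] * (n_samples - len(gts))
    return gts


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write a VCF, population map and annotation TSV reproducing the target tables.

    The classify -> bin -> count pipeline applied to the emitted files (focal
    population ``pop1``) yields exactly the per-bin tables in
    ``spec.targets``.  Output is deterministic for a given spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = spec.n_samples
    two_n = 2 * n
    mid = lambda b: 0.05 + 0.1 * b  # bin midpoint

    rows = []  # (focal_freq, other_freq, func_class)
    for b, (s_n, s_s, r_n, r_s) in sorted(spec.targets.items()):
        f = round(mid(b) * two_n) / two_n
        if not (0.1 * b) < f <= 0.1 * (b + 1):
            raise ValueError(
                f"bin {b} midpoint not representable with {n} samples"
            )
        other = round(spec.shared_other_freq * two_n) / two_n
        if not 0.0 < other < 1.0:
            raise ValueError("shared_other_freq must be strictly polymorphic")
        rows += [(f, other, "nonsynonymous")] * s_n
        rows += [(f, other, "synonymous")] * s_s
        rows += [(f, 0.0, "nonsynonymous")] * r_n
        rows += [(f, 0.0, "synonymous")] * r_s

    samples1 = [f"{spec.pop1}_{i}" for i in range(n)]
    samples2 = [f"{spec.pop2}_{i}" for i in range(n)]
    vcf_path = out_dir / "fixture.vcf"
    pop_path = out_dir / "fixture.popmap.tsv"
    ann_path = out_dir / "fixture.annotation.tsv"

    header = [
        "##fileformat=VCFv4.2",
        '##contig=<ID=1>',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples1 + samples2),
    ]
    vcf_lines = []
    ann_lines = ["chrom\tpos\tref\talt\tfunc_class\tgene_id"]
    for i, (f1, f2, fc) in enumerate(rows):
        pos = 1000 * (i + 1)
        gene = f"g{i % spec.n_genes}"
        g1 = _genotype_column(round(f1 * two_n), n)
        g2 = _genotype_column(round(f2 * two_n), n)
        vcf_lines.append(
            f"1\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(g1 + g2)
        )
        ann_lines.append(f"1\t{pos}\tA\tT\t{fc}\t{gene}")

    vcf_path.write_text("\n".join(header + vcf_lines) + "\n")
    pop_path.write_text(
        "sample\tpopulation\n"
        + "".join(f"{s}\t{spec.pop1}\n" for s in samples1)
        + "".join(f"{s}\t{spec.pop2}\n" for s in samples2)
    )
    ann_path.write_text("\n".join(ann_lines) + "\n")
    return vcf_path, pop_path, ann_path


# ---------------------------------------------------------------------------
# writers


def write_binned_counts(binned: BinnedCounts, path: str | Path) -> Path:
    """Tidy TSV of per-bin and pooled count tables."""
    path = Path(path)
    rows = []
    edges = binned.bin_edges
    for i, t in enumerate(binned.per_bin):
        rows.append(
            {
                "bin": f"{edges[i]:.1f}-{edges[i + 1]:.1f}",
                "s_n": t.s_n, "s_s": t.s_s, "r_n": t.r_n, "r_s": t.r_s,
                "flagged": bool(binned.flagged[i]) if binned.flagged else False,
            }
        )
    a = binned.combined_above
    rows.append(
        {"bin": ">0.1", "s_n": a.s_n, "s_s": a.s_s, "r_n": a.r_n, "r_s": a.r_s,
         "flagged": binned.combined_flagged}
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_binned_counts(path: str | Path) -> BinnedCounts:
    df = pd.read_csv(path, sep="\t")
    per = df[df["bin"] != ">0.1"]
    above = df[df["bin"] == ">0.1"].iloc[0]
    edges = np.linspace(0.0, 0.5, len(per) + 1)
    return BinnedCounts(
        bin_edges=edges,
        per_bin=[
            PolymorphismCounts(r.s_n, r.s_s, r.r_n, r.r_s) for r in per.itertuples()
        ],
        combined_above=PolymorphismCounts(above.s_n, above.s_s, above.r_n, above.r_s),
        flagged=list(per["flagged"].astype(bool)),
        combined_flagged=bool(above["flagged"]),
    )


def write_results(
    out_dir: str | Path,
    results: BalancingSelectionResults | None = None,
    binned: BinnedCounts | None = None,
    tables: pd.DataFrame | None = None,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write estimate/count TSVs plus a JSON manifest; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if results is not None:
        p = out_dir / "estimates.tsv"
        results.to_frame().to_csv(p, sep="\t", index=False)
        written["estimates"] = p
    if binned is not None:
        written["counts"] = write_binned_counts(binned, out_dir / "counts.tsv")
    if tables is not None:
        p = out_dir / "tables.tsv"
        tables.to_csv(p, sep="\t", index=False)
        written["tables"] = p
    mf = dict(manifest or {})
    mf.setdefault("package", "balsel")
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(mf, indent=2, default=str) + "\n")
    written["manifest"] = p
    return written
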