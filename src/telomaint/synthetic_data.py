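"""Seeded synthetic inputs with planted ground truth for every stage.

Each generator emulates the input contract of one pipeline stage and
returns, alongside the data, a machine-readable truth table describing
what was planted. One global seed drives independent per-stage substreams
derived by stable hashing of the stage name, so adding a stage never
perturbs another stage's draws; identical seed and parameters give
byte-identical serialized outputs.

The defaults mirror the study conditions the pipeline is designed for:
reads of 100 nt with telomeric fractions around 1e-4..1e-2 (the dynamic
range between exome and genome sequencing); a two-batch exome cohort with
a 1.5 log-unit location shift; allele counts at depths 30-100 with a 1%
RNA error rate for monoallelic loci; CpG pairs at ~20x coverage; 200-line
dependency screens with ~0.9 intra-module correlations and one-SD
mutation effects in 10% of lines; and methylation cohorts of 10,000
islands with a 0.3-beta hypomethylation planted in one annotated set.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import Region, RegionSet
from .telomere_content import TELOMERE_MOTIF, SequencingRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage random substream from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass
class SimulationConfig:
    """Global seed plus per-stage parameter overrides."""

    seed: int = 0
    reads: dict = field(default_factory=dict)
    content: dict = field(default_factory=dict)
    ase: dict = field(default_factory=dict)
    asm: dict = field(default_factory=dict)
    dependency: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reads


def gen_reads(
    seed: int = 0,
    n_reads: int = 200_000,
    read_length: int = 100,
    telomere_fraction: float = 1e-3,
    gc_target: float = 0.45,
    sample: str = "sim",
) -> tuple[list[str], dict]:
    """Simulate reads with a planted telomeric fraction.

    Telomeric reads are tandem TTAGGG repeats at a random phase;
    background reads are i.i.d. bases at the target GC composition.
    Read length must allow at least six full motifs.
    """
    if not 0.0 <= telomere_fraction <= 1.0:
        raise ValueError("telomere_fraction must be in [0, 1]")
    if read_length < 6 * len(TELOMERE_MOTIF):
        raise ValueError(
            f"read_length {read_length} cannot hold 6 copies of {TELOMERE_MOTIF}"
        )
    rng = stage_rng(seed, "reads")
    telomeric = rng.random(n_reads) < telomere_fraction
    n_tel = int(telomeric.sum())
    phases = rng.integers(0, len(TELOMERE_MOTIF), size=n_tel)
    tandem = TELOMERE_MOTIF * (read_length // len(TELOMERE_MOTIF) + 2)
    tel_seqs = iter(tandem[p : p + read_length] for p in phases)

    n_bg = n_reads - n_tel
    p_gc = gc_target / 2.0
    p_at = (1.0 - gc_target) / 2.0
    codes = rng.choice(4, size=(n_bg, read_length), p=[p_at, p_gc, p_gc, p_at])
    blob = _BASES[codes].tobytes().decode("ascii")
    bg_seqs = iter(
        blob[i * read_length : (i + 1) * read_length] for i in range(n_bg)
    )

    reads = [next(tel_seqs) if t else next(bg_seqs) for t in telomeric]
    truth = {
        "sample": sample,
        "n_reads": n_reads,
        "read_length": read_length,
        "telomere_fraction": telomere_fraction,
        "gc_target": gc_target,
        "planted_telomeric": n_tel,
    }
    return reads, truth


def write_fastq(reads: Sequence[str], path: str | Path, sample: str = "sim") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{sample}_read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def reads_as_records(
    reads: Sequence[str], sample: str = "sim", read_group: str = "rg0"
) -> list[SequencingRead]:
    return [SequencingRead(s, read_group=read_group, sample=sample) for s in reads]


# ---------------------------------------------------------------------------
# Batched content


def gen_batched_content(
    seed: int = 0,
    n_per_batch: int = 200,
    delta: float = 1.5,
    latent_mean: float = 2.0,
    latent_sd: float = 0.6,
    feature_gap: float = 2e-3,
    feature_sd: float = 1e-4,
) -> dict:
    """Two content tables sharing latent log2 contents, one with a planted
    two-batch location shift and batch-separated motif-frequency features.

    Returns a dict with 'reference' and 'batched' raw-length Series,
    'features' (freq4/5/6 per batched sample), and 'truth' (latent
    log-content and batch label per sample).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = stage_rng(seed, "content")
    n = 2 * n_per_batch
    samples = [f"CL{i:04d}" for i in range(n)]
    latent = rng.normal(latent_mean, latent_sd, size=n)
    batch = np.repeat([0, 1], n_per_batch)
    reference = pd.Series(2.0**latent, index=samples, name="raw_length_kb")
    batched = pd.Series(2.0 ** (latent + delta * batch), index=samples)
    base = np.array([3e-3, 2e-3, 1.5e-3])
    feats = (
        base[None, :]
        + feature_gap * batch[:, None]
        + rng.normal(0.0, feature_sd, size=(n, 3))
    )
    features = pd.DataFrame(
        np.clip(feats, 0.0, 1.0), index=samples, columns=["freq4", "freq5", "freq6"]
    )
    truth = pd.DataFrame({"latent_log2": latent, "batch": batch}, index=samples)
    return {
        "reference": reference,
        "batched": batched,
        "features": features,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Allele counts (ASE)


def gen_allele_counts(
    seed: int = 0,
    n_snps: int = 1000,
    depth_range: tuple[int, int] = (30, 100),
    epsilon: float = 0.01,
    mae_fraction: float = 0.5,
    gene: str = "TERT",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample DNA/RNA allele counts with planted MAE/BAE states.

    DNA counts are Binomial(depth, 0.5) (heterozygous); RNA counts are
    Binomial(depth, 0.5) for biallelic loci and Binomial(depth, eps) or
    (1 - eps) for monoallelic loci depending on the silenced allele.
    """
    lo, hi = depth_range
    if lo < 1:
        raise ValueError("depths must be >= 1")
    rng = stage_rng(seed, "ase")
    samples = [f"CL{i:04d}" for i in range(n_snps)]
    mae = rng.random(n_snps) < mae_fraction
    dna_depth = rng.integers(lo, hi + 1, size=n_snps)
    rna_depth = rng.integers(lo, hi + 1, size=n_snps)
    dna_ref = rng.binomial(dna_depth, 0.5)
    expressed_ref = rng.random(n_snps) < 0.5
    p_ref = np.where(mae, np.where(expressed_ref, 1.0 - epsilon, epsilon), 0.5)
    rna_ref = rng.binomial(rna_depth, p_ref)
    counts = pd.DataFrame(
        {
            "sample": samples,
            "gene": gene,
            "snp_id": [f"rs{i:06d}" for i in range(n_snps)],
            "chrom": "chr5",
            "pos": 1_253_000 + np.arange(n_snps),
            "dna_source": "WGS",
            "dna_ref": dna_ref,
            "dna_alt": dna_depth - dna_ref,
            "rna_ref": rna_ref,
            "rna_alt": rna_depth - rna_ref,
            "filter": "PASS",
        }
    )
    truth = pd.DataFrame(
        {
            "sample": samples,
            "gene": gene,
            "status": np.where(mae, "MAE", "BAE"),
            "expressed_allele": np.where(
                mae, np.where(expressed_ref, "ref", "alt"), "both"
            ),
        }
    )
    return counts, truth


# ---------------------------------------------------------------------------
# CpG pairs (ASM)


def gen_cpg_pairs(
    seed: int = 0,
    n_samples: int = 40,
    n_pairs: int = 50,
    coverage: int = 20,
    purity: float = 0.95,
    asm_fraction: float = 0.5,
    chrom: str = "chr5",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CpG-pair joint-state counts with planted ASM.

    For an ASM pair, each read is drawn from one of two alleles (one
    methylated, one not) and each CpG on the read follows the allele's
    state with probability ``purity``. Null pairs draw the two CpG states
    independently at 0.5, so mm/mu/um/uu are equally likely.
    """
    if not 0.5 <= purity <= 1.0:
        raise ValueError("purity must be in [0.5, 1]")
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = stage_rng(seed, "asm")
    asm_pair = rng.random(n_pairs) < asm_fraction
    positions = 1_250_000 + 40 * np.arange(n_pairs)
    rows = []
    for j in range(n_pairs):
        for i in range(n_samples):
            if asm_pair[j]:
                allele_meth = rng.random(coverage) < 0.5
                state_a = np.where(
                    rng.random(coverage) < purity, allele_meth, ~allele_meth
                )
                state_b = np.where(
                    rng.random(coverage) < purity, allele_meth, ~allele_meth
                )
            else:
                state_a = rng.random(coverage) < 0.5
                state_b = rng.random(coverage) < 0.5
            mm = int((state_a & state_b).sum())
            mu = int((state_a & ~state_b).sum())
            um = int((~state_a & state_b).sum())
            uu = int((~state_a & ~state_b).sum())
            rows.append(
                (
                    f"CL{i:04d}", chrom, int(positions[j]), int(positions[j]) + 20,
                    mm, mu, um, uu,
                )
            )
    pairs = pd.DataFrame(
        rows, columns=["sample", "chrom", "pos_a", "pos_b", "mm", "mu", "um", "uu"]
    )
    truth = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_a": positions,
            "pos_b": positions + 20,
            "asm": asm_pair,
            "purity": np.where(asm_pair, purity, np.nan),
        }
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# Dependency screens


def gen_dependency(
    seed: int = 0,
    n_genes: int = 50,
    n_samples: int = 200,
    module_size: int = 9,
    module_r: float = 0.9,
    n_mutation_genes: int = 1,
    n_mutants: int = 20,
    mutation_effect: float = -1.0,
) -> dict:
    """Dependency and mutation matrices with a planted codependent module
    and planted mutation effects.

    The first ``module_size`` genes share a latent factor giving pairwise
    correlations near ``module_r``; the last ``n_mutation_genes`` genes
    each get a paired binary mutation row whose mutants are shifted by
    ``mutation_effect`` (in noise-SD units) in that gene's dependency.
    """
    if module_size > n_genes:
        raise ValueError("module_size cannot exceed n_genes")
    if module_size + n_mutation_genes > n_genes:
        raise ValueError("module and mutation genes must not overlap")
    rng = stage_rng(seed, "dependency")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"CL{i:04d}" for i in range(n_samples)]
    dep = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    if module_size:
        latent = rng.normal(0.0, 1.0, size=n_samples)
        loading = np.sqrt(module_r)
        dep[:module_size] = (
            loading * latent[None, :]
            + np.sqrt(1.0 - module_r) * dep[:module_size]
        )
    mut_genes = genes[n_genes - n_mutation_genes :] if n_mutation_genes else []
    mut = np.zeros((n_mutation_genes, n_samples), dtype=int)
    for k in range(n_mutation_genes):
        idx = rng.choice(n_samples, size=n_mutants, replace=False)
        mut[k, idx] = 1
        dep_idx = n_genes - n_mutation_genes + k
        dep[dep_idx, idx] += mutation_effect
    dep_df = pd.DataFrame(dep, index=genes, columns=samples)
    mut_df = pd.DataFrame(mut, index=mut_genes, columns=samples)
    truth = {
        "module_genes": genes[:module_size],
        "mutation_genes": mut_genes,
        "mutation_effect": mutation_effect,
        "n_mutants": n_mutants,
    }
    return {"dependency": dep_df, "mutation": mut_df, "truth": truth}


# ---------------------------------------------------------------------------
# Methylation cohort (enrichment)


def gen_methylation_cohort(
    seed: int = 0,
    n_cgis: int = 10_000,
    n_mut: int = 40,
    n_wt: int = 160,
    effect: float = 0.3,
    n_decoys: int = 20,
    set_size: int = 400,
    cgi_width: int = 1_000,
    n_chroms: int = 23,
    chrom_length: int = 150_000_000,
    beta_mean: float = 0.6,
    beta_sd: float = 0.1,
) -> dict:
    """CGI methylation cohort with hypomethylation planted in one set.

    CGIs are placed uniformly on synthetic chromosomes; one annotated set
    coincides with a random subset of ``set_size`` CGIs, whose betas are
    reduced by ``effect`` in the "mutant" group; decoy sets coincide with
    random CGI subsets of the same size but carry no signal.
    """
    if n_decoys < 1:
        raise ValueError("need at least one decoy set")
    rng = stage_rng(seed, "enrichment")
    chroms = [f"chr{c + 1}" for c in range(n_chroms)]
    cgi_chrom = rng.integers(0, n_chroms, size=n_cgis)
    cgi_start = rng.integers(1, chrom_length - cgi_width, size=n_cgis)
    regions = [
        Region(f"CGI_{i:05d}", chroms[cgi_chrom[i]], int(cgi_start[i]),
               int(cgi_start[i]) + cgi_width - 1)
        for i in range(n_cgis)
    ]
    universe = RegionSet("universe", regions)
    by_name = {r.name: r for r in regions}

    planted_idx = rng.choice(n_cgis, size=set_size, replace=False)
    planted = RegionSet(
        "planted", [by_name[f"CGI_{i:05d}"] for i in planted_idx]
    )
    decoys = []
    for k in range(n_decoys):
        idx = rng.choice(n_cgis, size=set_size, replace=False)
        decoys.append(
            RegionSet(f"decoy_{k:02d}", [by_name[f"CGI_{i:05d}"] for i in idx])
        )

    n = n_mut + n_wt
    samples = [f"CL{i:04d}" for i in range(n)]
    labels = pd.Series(
        ["mutant"] * n_mut + ["wildtype"] * n_wt, index=samples, name="tertp"
    )
    betas = rng.normal(beta_mean, beta_sd, size=(n, n_cgis))
    betas[:n_mut, planted_idx] -= effect
    betas = np.clip(betas, 0.0, 1.0)
    meth = pd.DataFrame(
        betas, index=samples, columns=[r.name for r in regions]
    )
    truth = {
        "planted_set": "planted",
        "planted_cgis": sorted(f"CGI_{i:05d}" for i in planted_idx),
        "effect": effect,
    }
    chrom_sizes = {c: chrom_length for c in chroms}
    return {
        "methylation": meth,
        "labels": labels,
        "universe": universe,
        "planted": planted,
        "decoys": decoys,
        "chrom_sizes": chrom_sizes,
        "truth": truth,
    }
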