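"""End-to-end synthetic pipeline run with a reproducibility manifest.

``run_pipeline`` chains the generators to every analysis stage under one
recorded RNG seed: simulate -> topology -> tdprop -> seedscan ->
missingness, writing one JSON report per stage plus a manifest holding the
package version, the seed, and a SHA-256 digest of every file produced.
Identical configurations produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

from tdprogram import __version__, fileio, missingness, poisson, qpcr, seedguide, synthetic
from tdprogram.errors import DataError


@dataclass
class RunConfig:
    """Parameters of a full synthetic run; defaults mirror the study design.

    The TD-chase defaults (m = 0.5 per 20-min cycle) and the seed-search
    defaults (13 bp minimum seed, NGG PAM, 20 nt spacer) are the study's
    stated conditions; cohort and gene-set sizes are desk-scale.
    """

    rng_seed: int = 0
    output_dir: str | Path = "tdprogram-run"
    log_level: str = "INFO"
    # seedscan / simulate
    n_genes: int = 10
    gene_len: int = 500
    seed_len: int = 15
    n_carriers: int = 4
    min_seed_len: int = 13
    pam: str = "NGG"
    spacer_len: int = 20
    min_carriers: int = 2
    # topology
    noise_sd: float = 0.0
    n_replicates: int = 3
    convention: qpcr.Convention = "printed"
    # tdprop
    n_cells: int = 10_000
    m: float = 0.5
    n_cycles: int = 1
    precondition_multiplier: float = 1.0
    # missingness
    n_lost: int = 30
    n_retained: int = 50
    n_denovo: int = 20
    timepoints: tuple = ("t0", "t5", "t10", "t15", "t20", "t50")


#: Zone fractions used by the synthetic topology stage: a locus relaxing
#: from an sc+-dominated to an sc--dominated distribution.
DEFAULT_ZONE_FRACTIONS = {
    ("locusA", 0.0): (0.1, 0.2, 0.3, 0.4),
    ("locusA", 2.0): (0.4, 0.3, 0.2, 0.1),
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic inputs; return the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    written: list[Path] = []

    def emit(name: str, obj: dict) -> None:
        path = out / name
        fileio.write_json(obj, path, rng_seed=seed)
        written.append(path)

    # --- simulate + seedscan -------------------------------------------
    planted = synthetic.gen_genes_with_seed(
        config.n_genes, config.gene_len, config.seed_len, config.n_carriers,
        rng_seed=seed,
    )
    fasta = out / "genes.fasta"
    fileio.write_fasta(planted.genes, fasta)
    written.append(fasta)
    params = seedguide.SeedParameters(
        min_seed_len=config.min_seed_len,
        pam=config.pam,
        spacer_len=config.spacer_len,
        min_carriers=config.min_carriers,
    )
    clusters = seedguide.find_shared_seeds(planted.genes, params)
    if not clusters:
        raise DataError("seedscan found no shared seed in the planted gene set")
    top = clusters[0]
    design = seedguide.design_guide(top, params, genes=planted.genes)
    bed = out / "cut_sites.bed"
    fileio.write_bed(seedguide.cut_sites(top), bed)
    written.append(bed)
    emit(
        "seedscan.json",
        {
            "truth_seed": planted.truth_seed,
            "truth_carriers": sorted(planted.carriers),
            "n_clusters": len(clusters),
            "top_seed": top.seed_seq,
            "top_carriers": sorted(top.carriers),
            "expected_random": top.expected_random,
            "spacer": design.spacer,
            "full_sgrna": design.full_sgrna,
            "n_padded": design.n_padded,
            "recovered": planted.truth_seed in top.seed_seq
            and top.carriers == planted.carriers,
        },
    )

    # --- topology -------------------------------------------------------
    ct_records = synthetic.gen_ct_table(
        DEFAULT_ZONE_FRACTIONS,
        noise_sd=config.noise_sd,
        n_replicates=config.n_replicates,
        rng_seed=seed,
        convention=config.convention,
    )
    ct_path = out / "ct_table.tsv"
    fileio.write_ct_table(ct_records, ct_path)
    written.append(ct_path)
    dists = qpcr.zone_distributions(ct_records, convention=config.convention)
    by_time = {d.timepoint: d for d in dists}
    shift = (
        qpcr.topology_shift(by_time[0.0], by_time[2.0])
        if {0.0, 2.0} <= set(by_time)
        else None
    )
    emit(
        "topology.json",
        {
            "convention": config.convention,
            "distributions": [
                {
                    "locus": d.locus,
                    "timepoint_min": d.timepoint,
                    "fractions": [float(x) for x in d.fractions],
                }
                for d in dists
            ],
            "topology_shift_t0_to_t2": shift,
        },
    )

    # --- tdprop ---------------------------------------------------------
    cohort = synthetic.gen_td_chase(
        config.n_cells, config.m, config.n_cycles,
        config.precondition_multiplier, rng_seed=seed,
    )
    cohort_path = out / "td_chase.tsv"
    fileio.write_cohort(cohort, cohort_path)
    written.append(cohort_path)
    counts = poisson.ChaseCounts(
        total=cohort.n_cells,
        converted=cohort.cumulative[-1],
        cycles=cohort.n_cycles,
    )
    emit("tdprop.json", {"true_m": config.m, **poisson.report(counts)})

    # --- missingness ----------------------------------------------------
    matrix, truth = synthetic.gen_presence_matrix(
        config.n_lost, config.n_retained, config.n_denovo,
        config.timepoints, rng_seed=seed,
    )
    presence_path = out / "presence.tsv"
    fileio.write_presence(matrix, presence_path)
    written.append(presence_path)
    labels = missingness.extract_clusters(matrix)
    emit(
        "missingness.json",
        {
            **missingness.summary(matrix, baseline=config.timepoints[0]),
            "truth_recovered": bool((labels == truth).all()),
        },
    )

    # --- manifest -------------------------------------------------------
    manifest = {
        "version": __version__,
        "rng_seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "files": {p.name: fileio.sha256_of(p) for p in sorted(written)},
    }
    fileio.write_json(manifest, out / "manifest.json")
    return manifest
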