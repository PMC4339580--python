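"""End-to-end driver: normalize, contrast, profile, classify, enrich.

The stages run in the analysis order the study design dictates: trimmed-mean
normalization; six pairwise contrasts plus interaction and main-effect tests;
headline differential-expression lists and the Venn partition of the three
contrasts against the inactive wild-type baseline; discretized profile codes
and their tabulation among interaction-significant genes; per-gene
synergistic/antagonistic calls; and, when a gene-set collection is supplied,
EASE enrichment of the per-contrast DE lists and of large profile clusters.

All outputs are TSV plus a JSON manifest (config echo, package version, stage
row counts) that suffices to re-run the pipeline identically; two runs with
the same config produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

from factorial_de import io as fio
from factorial_de.contrasts import (
    CONTRASTS,
    run_pairwise_contrasts,
    select_de_genes,
    test_interaction,
    test_main_effects,
)
from factorial_de.enrichment import cluster_terms, enrich_terms
from factorial_de.normalization import normalize
from factorial_de.profiles import (
    call_interactions,
    interaction_effects,
    profile_codes,
    tabulate_profiles,
    venn_partition,
)

#: The Venn triplet of Fig-style baseline comparisons: IW vs each other group.
DEFAULT_VENN_TRIPLET = ("IW-AW", "IW-AM", "IW-IM")


@dataclass
class PipelineConfig:
    counts_path: str = ""
    design_path: str = ""
    gmt_path: str | None = None
    output_dir: str = "results"
    # thresholds
    interaction_q: float = 0.005
    exclusion_q: float = 0.005
    de_q: float = 0.005
    lfc_cutoff: float = 1.3
    discretize_p: float = 1e-4
    profile_min_size: int = 50
    enrich_min_profile: int = 100
    cluster_score_cutoff: float = 3.0
    kappa_threshold: float = 0.35
    kappa_seed_min_size: int = 3
    kappa_merge_overlap: float = 0.5
    mode_epsilon: float = 0.1
    # numerics
    pseudocount: float = 1.0
    trim_fraction: float = 0.05
    venn_triplet: tuple[str, str, str] = DEFAULT_VENN_TRIPLET
    enrich: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("interaction_q", "exclusion_q", "de_q", "discretize_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} = {v} outside (0, 1]")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError(f"trim_fraction = {self.trim_fraction} outside [0, 0.5)")
        if self.lfc_cutoff < 0 or self.pseudocount < 0:
            raise ValueError("lfc_cutoff and pseudocount must be non-negative")
        if self.profile_min_size < 1 or self.enrich_min_profile < 1:
            raise ValueError("profile size cutoffs must be >= 1")
        bad = set(self.venn_triplet) - set(CONTRASTS)
        if bad:
            raise ValueError(f"unknown contrast(s) in venn_triplet: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "venn_triplet" in raw:
            raw["venn_triplet"] = tuple(raw["venn_triplet"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    if config.enrich and config.gmt_path is None:
        raise ValueError("enrichment enabled but no GMT path supplied")
    collection = None
    if config.enrich:
        collection = fio.read_gmt(config.gmt_path)

    matrix = fio.read_counts(config.counts_path)
    design = fio.read_design(config.design_path)
    extra = sorted(set(design.table.index) - set(matrix.sample_ids))
    if extra:
        raise ValueError(f"[read] design samples missing from matrix: {extra}")
    log("read", f"{len(matrix.gene_ids)} genes x {len(matrix.sample_ids)} samples")

    out = config.output_dir
    os.makedirs(out, exist_ok=True)

    norm = normalize(matrix, config.trim_fraction)
    fio.write_normalized(norm, os.path.join(out, "normalized.tsv"))
    log("normalize", f"size factors for {len(norm.size_factors)} samples")

    pairwise = run_pairwise_contrasts(norm, design, config.pseudocount)
    for name, res in pairwise.items():
        fio.write_contrast(res, os.path.join(out, f"contrast_{name}.tsv"))
    interaction = test_interaction(norm, design, config.pseudocount)
    interaction.to_csv(os.path.join(out, "interaction.tsv"), sep="\t")
    main_geno, main_act, excluded = test_main_effects(
        norm, design, interaction["q"], config.exclusion_q, config.pseudocount
    )
    fio.write_contrast(main_geno, os.path.join(out, "main_genotype.tsv"))
    fio.write_contrast(main_act, os.path.join(out, "main_activity.tsv"))
    n_inter = int((interaction["q"] < config.interaction_q).sum())
    log("contrasts", f"{n_inter} genes with interaction q < {config.interaction_q}")

    de_lists: dict[str, list[str]] = {}
    for name, res in pairwise.items():
        de_lists[name] = select_de_genes(res, config.de_q, config.lfc_cutoff)
    de_lists["main_genotype"] = select_de_genes(main_geno, config.de_q, config.lfc_cutoff)
    de_lists["main_activity"] = select_de_genes(main_act, config.de_q, config.lfc_cutoff)
    for name, genes in de_lists.items():
        with open(os.path.join(out, f"de_{name}.txt"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(genes) + ("\n" if genes else ""))
    log("de", "; ".join(f"{k}:{len(v)}" for k, v in sorted(de_lists.items())))

    va, vb, vc = config.venn_triplet
    venn = venn_partition(de_lists[va], de_lists[vb], de_lists[vc])
    with open(os.path.join(out, "venn.tsv"), "w", encoding="utf-8") as fh:
        fh.write("region\tsize\tgenes\n")
        for region, size in venn.sizes.items():
            genes = ",".join(sorted(getattr(venn, region)))
            fh.write(f"{region}\t{size}\t{genes}\n")
    log("venn", f"{va}/{vb}/{vc}: " + ", ".join(f"{k}={v}" for k, v in venn.sizes.items()))

    inter_genes = interaction.index[interaction["q"] < config.interaction_q]
    codes = profile_codes(pairwise, config.discretize_p).loc[inter_genes]
    all_clusters = tabulate_profiles(codes, min_size=1)
    reported = all_clusters[all_clusters["count"] >= config.profile_min_size]
    reported_out = reported.copy()
    reported_out["genes"] = reported_out["genes"].map(",".join)
    reported_out.to_csv(os.path.join(out, "profiles.tsv"), sep="\t", index=False)
    log(
        "profiles",
        f"{len(all_clusters)} distinct codes over {len(codes)} interaction genes; "
        f"{len(reported)} clusters of >= {config.profile_min_size}",
    )

    effects = interaction_effects(norm, design, config.pseudocount)
    calls = call_interactions(effects, interaction, config.interaction_q, config.mode_epsilon)
    calls.to_csv(os.path.join(out, "interaction_calls.tsv"), sep="\t")
    n_syn = int((calls["mode"] == "synergistic").sum())
    n_ant = int((calls["mode"] == "antagonistic").sum())
    log("classify", f"{n_syn} synergistic, {n_ant} antagonistic")

    enrichment_counts: dict[str, int] = {}
    if config.enrich:
        targets: dict[str, list[str]] = {
            f"de_{name}": genes for name, genes in de_lists.items()
        }
        big = all_clusters[all_clusters["count"] > config.enrich_min_profile]
        for _, row in big.iterrows():
            targets[f"profile_{row['code'].replace(',', '')}"] = row["genes"]
        for label, genes in targets.items():
            usable = set(genes) & collection.background
            if not usable:
                enrichment_counts[label] = 0
                continue
            terms = enrich_terms(usable, collection)
            terms.to_csv(os.path.join(out, f"enrichment_{label}.tsv"), sep="\t")
            clusters = [
                c
                for c in cluster_terms(
                    terms,
                    collection,
                    config.kappa_threshold,
                    config.kappa_seed_min_size,
                    config.kappa_merge_overlap,
                )
                if c.score > config.cluster_score_cutoff
            ]
            with open(
                os.path.join(out, f"clusters_{label}.tsv"), "w", encoding="utf-8"
            ) as fh:
                fh.write("rank\tscore\tmembers\n")
                for rank, cl in enumerate(clusters, start=1):
                    fh.write(f"{rank}\t{cl.score:.2f}\t{','.join(cl.members)}\n")
            enrichment_counts[label] = len(terms)
        log("enrich", "; ".join(f"{k}:{v}" for k, v in sorted(enrichment_counts.items())))

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "version": _version(),
        "n_genes": len(matrix.gene_ids),
        "n_samples": len(matrix.sample_ids),
        "n_interaction_significant": n_inter,
        "n_excluded_from_main": int(excluded.sum()),
        "de_counts": {k: len(v) for k, v in de_lists.items()},
        "venn_sizes": venn.sizes,
        "n_profiled": int(len(codes)),
        "profile_cluster_sizes_sum": int(all_clusters["count"].sum()),
        "n_synergistic": n_syn,
        "n_antagonistic": n_ant,
        "enrichment_term_counts": enrichment_counts,
    }
    with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out, "log.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return manifest


def _version() -> str:
    from factorial_de import __version__

    return __version__
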