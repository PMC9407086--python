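"""End-to-end orchestration: simulate or load data, then run the
forensic, distance, haplogroup and network stages into one report.

The report is a plain JSON-serializable dictionary with one section per
enabled stage plus a provenance block (config hash, seed, package
version).  Given the same configuration and seed the report is
byte-identical across runs — no timestamps enter it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .distance import mds, neighbor_joining, rst_matrix
from .forensic import (
    forensic_parameters,
    gene_diversity,
    haplotype_spectrum,
    locus_frequencies,
    round_half_up,
    variant_screen,
)
from .haplogroups import (
    HaplogroupTree,
    builtin_tree,
    call_haplogroup,
    clade_frequency,
    haplogroup_frequencies,
    pca,
)
from .io import read_snp_table, read_str_table, write_newick
from .network import (
    NET_LOCI,
    ancestral_node,
    build_network,
    collect_net_haplotypes,
    network_composition_summary,
    weights_from_rates,
)
from .panels import get_panel
from .profiles import SNPProfile, STRProfile
from .rates import DEFAULT_MUTATION_RATES, read_rate_table
from .simulate import SimConfig, simulate_divergent_pair

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_ALL_STAGES = ("forensic", "distance", "haplogroup", "network")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either point ``str_table``/``snp_table`` at genotype tables, or leave
    them unset to simulate a divergent population pair with
    ``sim_options`` overrides (see :class:`ylineage.simulate.SimConfig`).
    """

    str_table: str | None = None
    snp_table: str | None = None
    sim_options: dict = field(default_factory=dict)
    panels: list[str] = field(
        default_factory=lambda: ["yfiler", "ppy23", "yfiler_plus", "yfiler_platinum"]
    )
    rst_loci: list[str] | None = None
    network_loci: list[str] = field(default_factory=lambda: list(NET_LOCI))
    network_haplogroup: str | None = None
    tree_file: str | None = None
    rate_table: str | None = None
    outdir: str = "ylineage_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))

    def validate(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {_ALL_STAGES}")
        for path in (self.str_table, self.snp_table, self.tree_file, self.rate_table):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        for name in self.panels:
            get_panel(name)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _by_population(profiles):
    pops: dict[str, list] = {}
    for p in profiles:
        pops.setdefault(p.population, []).append(p)
    return pops


def _load_or_simulate(config: RunConfig, tree: HaplogroupTree
                      ) -> tuple[list[STRProfile], list[SNPProfile]]:
    if config.str_table is not None:
        panel = get_panel(config.panels[-1])
        strs = read_str_table(config.str_table, panel)
        snps = read_snp_table(config.snp_table) if config.snp_table else []
        return strs, snps
    sim_kwargs = dict(config.sim_options)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimConfig(**sim_kwargs)
    out_a, out_b = simulate_divergent_pair(sim, tree=tree)
    return (
        out_a.str_profiles + out_b.str_profiles,
        out_a.snp_profiles + out_b.snp_profiles,
    )


def _forensic_stage(str_pops, config: RunConfig, outdir: Path) -> dict:
    section: dict = {"parameters": {}, "gene_diversity": {}, "variants": {}}
    big_panel = get_panel(config.panels[-1])
    for pop, profiles in str_pops.items():
        for panel_name in config.panels:
            panel = get_panel(panel_name)
            spec = haplotype_spectrum(profiles, panel, population=pop)
            params = forensic_parameters(spec)
            section["parameters"].setdefault(pop, {})[panel_name] = {
                "spectrum": {str(k): v for k, v in spec.spectrum.items()},
                **params.rounded(5),
            }
        gd = {}
        for locus in big_panel.loci:
            try:
                gd[locus] = round_half_up(
                    gene_diversity(locus_frequencies(profiles, locus)), 4
                )
            except ValueError:
                logger.info("no usable calls for GD at %s in %s", locus, pop)
        section["gene_diversity"][pop] = gd
        report = variant_screen(profiles, big_panel)
        section["variants"][pop] = {
            "microvariants": [
                [s, l, list(map(float, k))] for s, l, k in report.microvariants
            ],
            "cnvs": [[s, l, list(map(float, k))] for s, l, k in report.cnvs],
            "nulls": [list(rec) for rec in report.nulls],
        }
    return section


def _distance_stage(str_pops, config: RunConfig, outdir: Path) -> dict:
    if len(str_pops) < 2:
        logger.info("distance stage skipped: fewer than 2 populations")
        return {"skipped": "fewer than 2 populations"}
    loci = config.rst_loci or [
        l for l in get_panel("yfiler").single_copy_loci()
    ]
    dist = rst_matrix(str_pops, loci)
    dist.write(outdir / "rst_matrix.tsv")
    section: dict = {
        "loci": loci,
        "labels": dist.labels,
        "rst": [[round(v, 6) for v in row] for row in dist.values.tolist()],
    }
    if len(str_pops) >= 3:
        result = mds(dist)
        result.coordinates.to_csv(outdir / "mds_coordinates.tsv", sep="\t")
        section["mds"] = {
            "stress": round(result.stress, 6),
            "converged": result.converged,
            "coordinates": {
                label: [round(v, 6) for v in row]
                for label, row in result.coordinates.iterrows()
            },
        }
        tree = neighbor_joining(dist)
        write_newick(tree, outdir / "nj_tree.nwk")
        section["nj_newick"] = str(tree)
    else:
        logger.info("MDS/NJ skipped: need >= 3 populations")
    return section


def _haplogroup_stage(snp_pops, tree: HaplogroupTree, outdir: Path) -> dict:
    section: dict = {"frequencies": {}, "clade_aggregates": {}, "calls": {}}
    freq_vectors = {}
    for pop, profiles in snp_pops.items():
        calls = [call_haplogroup(p, tree) for p in profiles]
        vec = haplogroup_frequencies(calls, population=pop)
        freq_vectors[pop] = vec
        section["calls"][pop] = {c.sample_id: c.label for c in calls}
        section["frequencies"][pop] = vec.rounded(2)
        aggregates = {}
        for clade in ("C", "D", "N", "O", "O1a", "O1b", "O2", "O2a2", "O2a2b", "QR"):
            if clade in tree:
                aggregates[clade] = round_half_up(
                    clade_frequency(vec, clade, tree), 2
                )
        section["clade_aggregates"][pop] = aggregates
    if len(freq_vectors) >= 3:
        import pandas as pd

        labels = sorted({l for v in freq_vectors.values() for l in v.percent})
        table = pd.DataFrame(
            {l: [freq_vectors[p].percent.get(l, 0.0) for p in freq_vectors]
             for l in labels},
            index=list(freq_vectors),
        )
        scores, var_exp = pca(table)
        scores.to_csv(outdir / "haplogroup_pca.tsv", sep="\t")
        section["pca"] = {
            "variance_explained": [round(v, 3) for v in var_exp.tolist()],
            "scores": {
                label: [round(v, 6) for v in row]
                for label, row in scores.iterrows()
            },
        }
    else:
        logger.info("haplogroup PCA skipped: need >= 3 populations")
    return section


def _network_stage(str_profiles, snp_pops, tree: HaplogroupTree,
                   config: RunConfig, rates: dict, outdir: Path) -> dict:
    # restrict to the members of the focal haplogroup (default: the most
    # frequent called clade across populations)
    calls: dict[str, str] = {}
    for profiles in snp_pops.values():
        for p in profiles:
            calls[p.sample_id] = call_haplogroup(p, tree).label
    if not calls:
        return {"skipped": "no SNP profiles for haplogroup restriction"}
    focal = config.network_haplogroup
    if focal is None:
        counts: dict[str, int] = {}
        for label in calls.values():
            if label != "unresolved":
                counts[label] = counts.get(label, 0) + 1
        focal = max(counts, key=lambda k: (counts[k], k))
    members = {s for s, label in calls.items() if label == focal}
    loci = tuple(config.network_loci)
    haplos = collect_net_haplotypes(str_profiles, loci, keep_samples=members)
    if len(haplos) < 2:
        return {"skipped": f"fewer than 2 distinct haplotypes in {focal}"}
    weights = weights_from_rates(rates, loci)
    net = build_network(haplos, weights)
    anc = ancestral_node(haplos, weights)
    summary = network_composition_summary(net, anc)
    nodes_rows = []
    for vec, data in net.nodes():
        nodes_rows.append({
            "vector": "-".join(map(str, vec)),
            "is_median": data["is_median"],
            **{f"n_{p}": c for p, c in sorted(data["counts"].items())},
        })
    import pandas as pd

    pd.DataFrame(nodes_rows).to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
    edge_rows = [
        {"u": "-".join(map(str, u)), "v": "-".join(map(str, v)),
         "length": d["length"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(edge_rows).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    return {
        "haplogroup": focal,
        "loci": list(loci),
        "weights": {w.locus: w.weight for w in weights},
        "n_haplotypes": sum(1 for _ in net.nodes(medians=False)),
        "n_medians": len(net.median_vectors),
        "spanning_cost": net.spanning_cost,
        "ancestral_haplotype": "-".join(map(str, anc)),
        "composition": summary,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the report dictionary.

    The report is also written to ``<outdir>/report.json`` along with the
    per-stage TSV/Newick artifacts.  A stage failure raises with the
    stage name; artifacts of completed stages remain on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = (
        HaplogroupTree.read(config.tree_file) if config.tree_file else builtin_tree()
    )
    rates = (
        read_rate_table(config.rate_table) if config.rate_table
        else dict(DEFAULT_MUTATION_RATES)
    )
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        }
    }
    str_profiles, snp_profiles = _load_or_simulate(config, tree)
    str_pops = _by_population(str_profiles)
    snp_pops = _by_population(snp_profiles)
    report["populations"] = {
        pop: len(profiles) for pop, profiles in str_pops.items()
    }

    for stage in config.stages:
        try:
            if stage == "forensic":
                report["forensic"] = _forensic_stage(str_pops, config, outdir)
            elif stage == "distance":
                report["distance"] = _distance_stage(str_pops, config, outdir)
            elif stage == "haplogroup":
                if snp_pops:
                    report["haplogroup"] = _haplogroup_stage(snp_pops, tree, outdir)
                else:
                    report["haplogroup"] = {"skipped": "no SNP table"}
            elif stage == "network":
                report["network"] = _network_stage(
                    str_profiles, snp_pops, tree, config, rates, outdir
                )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
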