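"""Config-driven orchestration of the full analysis.

A single YAML/JSON document enables and parameterizes the five stages in
dependency order — screen (domain-hit filtering, redundancy clustering,
reverse-best-hit orthology), synteny (outgroup anchoring, block detection),
rates (clade/domain NG86 summaries), models (codon-model fits, LRTs with
Benjamini–Hochberg correction) and divergence (type-I test and site
selection). Every threshold defaults to the screening/anchoring values used
throughout the package (E 1e-2 and 1e-3, 50% domain coverage, 0.95/0.6
clustering, 1e-10 anchoring, alpha 0.05) and is overridable per run.

Outputs are plain TSV tables per stage plus a JSON manifest and a run log
recording parameters and seeds; a stage failure aborts the run with a
stage-attributed error and leaves a FAILED marker next to the partial
outputs. Re-running with the same config and seed reproduces every table
byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .codonml import (NESTED_PAIRS, bh_adjust, fit_model_series,
                      likelihood_ratio_test)
from .core_io import (DomainPartition, read_alignment, read_codon_alignment,
                      read_fasta, read_gene_loci, read_newick)
from .divergence import estimate_type1_divergence, select_divergent_sites
from .homology import (assign_orthologs, cluster_redundant_sequences,
                       filter_domain_hits, read_blast_tab, read_domtblout)
from .rates import clade_rate_summary
from .synteny import (anchor_paralog_families, detect_syntenic_blocks,
                      loci_from_table, ParalogFamily, shared_pair_count)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config",
           "make_demo_config"]

STAGE_ORDER = ("screen", "synteny", "rates", "models", "divergence")

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "stages"},
    "stages": set(STAGE_ORDER),
    "screen": {
        "enabled", "domtblout", "dom_evalue_kind", "seq_e_max", "dom_e_max",
        "min_coverage", "sequences", "cluster_identity",
        "cluster_short_coverage", "forward_hits", "reverse_hits",
        "queries", "ortholog_e_max",
    },
    "synteny": {
        "enabled", "loci_a", "loci_b", "families", "outgroup_hits",
        "anchor_e_max", "window_size", "min_pairs",
    },
    "rates": {
        "enabled", "codon_alignment", "clades", "partitions", "reference_id",
        "omega_mode", "genetic_code",
    },
    "models": {
        "enabled", "codon_alignment", "tree", "families", "omega_starts",
        "frequencies", "genetic_code", "lrt_alpha",
    },
    "divergence": {
        "enabled", "alignment", "tree", "cluster_a", "cluster_b",
        "alpha", "n_bootstrap", "count_method",
    },
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    output_dir: str = "wgdtrace_out"
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        _check_keys("", doc, _SCHEMA[""])
        stages = doc.get("stages", {}) or {}
        _check_keys("stages", stages, _SCHEMA["stages"])
        for name, sub in stages.items():
            _check_keys(name, sub or {}, _SCHEMA[name])
        return cls(
            seed=int(doc.get("seed", 0)),
            output_dir=str(doc.get("output_dir", "wgdtrace_out")),
            stages={k: dict(v or {}) for k, v in stages.items()},
        )


def _check_keys(section: str, doc: Mapping[str, Any], allowed: set[str]):
    unknown = set(doc) - allowed
    if unknown:
        where = section or "top level"
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.from_dict(doc or {})


def _require(stage: str, cfg: Mapping[str, Any], key: str) -> str:
    if key not in cfg:
        raise PipelineError(stage, f"missing required setting {key!r}")
    path = cfg[key]
    if isinstance(path, str) and not Path(path).exists():
        raise PipelineError(stage, f"input file not found: {path}")
    return path


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _run_screen(cfg, outdir: Path) -> list[str]:
    outputs = []
    if "domtblout" in cfg:
        hits = read_domtblout(_require("screen", cfg, "domtblout"),
                              dom_evalue=cfg.get("dom_evalue_kind",
                                                 "conditional"))
        kept = filter_domain_hits(
            hits,
            seq_e_max=float(cfg.get("seq_e_max", 1e-2)),
            dom_e_max=float(cfg.get("dom_e_max", 1e-2)),
            min_coverage=float(cfg.get("min_coverage", 0.5)),
        )
        _write_tsv(
            outdir / "domain_hits.tsv",
            ["target_id", "query_domain", "seq_evalue", "dom_evalue",
             "hmm_from", "hmm_to", "hmm_length", "coverage"],
            [[h.target_id, h.query_domain, h.seq_evalue, h.dom_evalue,
              h.hmm_from, h.hmm_to, h.hmm_length,
              f"{h.hmm_coverage:.4f}"] for h in kept],
        )
        outputs.append("domain_hits.tsv")
    if "sequences" in cfg:
        seqs = read_fasta(_require("screen", cfg, "sequences"))
        clusters = cluster_redundant_sequences(
            seqs,
            identity_min=float(cfg.get("cluster_identity", 0.95)),
            short_coverage_min=float(cfg.get("cluster_short_coverage", 0.6)),
        )
        _write_tsv(
            outdir / "clusters.tsv",
            ["representative_id", "member_ids"],
            [[c.representative_id, ",".join(c.member_ids)] for c in clusters],
        )
        outputs.append("clusters.tsv")
    if "forward_hits" in cfg:
        forward = read_blast_tab(_require("screen", cfg, "forward_hits"))
        reverse_flat = read_blast_tab(_require("screen", cfg, "reverse_hits"))
        reverse: dict[str, list] = {}
        for h in reverse_flat:
            reverse.setdefault(h.query_id, []).append(h)
        queries = cfg.get("queries") or sorted({h.query_id for h in forward})
        e_max = float(cfg.get("ortholog_e_max", 1e-3))
        rows = []
        for q in queries:
            fwd_q = [h for h in forward if h.query_id == q]
            cand = {h.subject_id for h in fwd_q if h.evalue <= e_max}
            table = {s: reverse.get(s, []) for s in cand}
            orths = assign_orthologs(q, fwd_q, table, e_max=e_max)
            for s in sorted(orths):
                rows.append([q, s])
        _write_tsv(outdir / "orthologs.tsv", ["query_id", "ortholog_id"], rows)
        outputs.append("orthologs.tsv")
    return outputs


def _run_synteny(cfg, outdir: Path) -> list[str]:
    fam_rows = Path(_require("synteny", cfg, "families")).read_text()
    members: dict[str, list[str]] = {}
    for line in fam_rows.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fam, member = line.split("\t")[:2]
        members.setdefault(fam, []).append(member)
    families = [
        ParalogFamily(family_id=f, member_ids=tuple(m))
        for f, m in members.items()
    ]
    if "outgroup_hits" in cfg:
        hits = read_blast_tab(_require("synteny", cfg, "outgroup_hits"))
        families = anchor_paralog_families(
            families, hits, e_max=float(cfg.get("anchor_e_max", 1e-10))
        )
    fam_of = {m: f.family_id for f in families for m in f.member_ids}
    loci_a = loci_from_table(
        read_gene_loci(_require("synteny", cfg, "loci_a")), fam_of
    )
    loci_b = loci_from_table(
        read_gene_loci(_require("synteny", cfg, "loci_b")), fam_of
    )
    blocks = detect_syntenic_blocks(
        loci_a, loci_b, families,
        window_size=int(cfg.get("window_size", 100)),
        min_pairs=int(cfg.get("min_pairs", 3)),
    )
    _write_tsv(
        outdir / "synteny_blocks.tsv",
        ["block", "orientation", "n_pairs", "span_a", "span_b", "pairs"],
        [
            [i + 1, b.orientation, b.n_pairs,
             f"{b.span_a[0]}-{b.span_a[1]}", f"{b.span_b[0]}-{b.span_b[1]}",
             ";".join(f"{a.gene_id}|{bb.gene_id}" for a, bb in b.pairs)]
            for i, b in enumerate(blocks)
        ],
    )
    _write_tsv(
        outdir / "synteny_summary.tsv",
        ["n_blocks", "total_distinct_pairs"],
        [[len(blocks), shared_pair_count(blocks)]],
    )
    return ["synteny_blocks.tsv", "synteny_summary.tsv"]


def _run_rates(cfg, outdir: Path) -> list[str]:
    aln = read_codon_alignment(
        _require("rates", cfg, "codon_alignment"),
        genetic_code=int(cfg.get("genetic_code", 1)),
    )
    clades: dict[str, list[str]] = {}
    for line in Path(_require("rates", cfg, "clades")).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        seq_id, clade = line.split("\t")[:2]
        clades.setdefault(clade, []).append(seq_id)
    partitions = None
    if "partitions" in cfg:
        partitions = []
        for line in Path(_require("rates", cfg, "partitions")).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, start, end = line.split("\t")[:3]
            partitions.append(DomainPartition(name, int(start), int(end)))
    summaries = clade_rate_summary(
        aln, clades, partitions=partitions,
        reference_id=cfg.get("reference_id"),
        omega_mode=cfg.get("omega_mode", "ratio_of_means"),
    )
    _write_tsv(
        outdir / "clade_rates.tsv",
        ["clade", "partition", "mean_dN", "mean_dS", "omega", "n_pairs",
         "n_undefined"],
        [
            [s.clade, s.partition or "full",
             _fmt(s.mean_dN), _fmt(s.mean_dS), _fmt(s.omega),
             s.n_pairs, s.n_undefined]
            for s in summaries
        ],
    )
    return ["clade_rates.tsv"]


def _fmt(x) -> str:
    return "NA" if x is None else f"{x:.6f}"


def _run_models(cfg, outdir: Path) -> list[str]:
    aln = read_codon_alignment(
        _require("models", cfg, "codon_alignment"),
        genetic_code=int(cfg.get("genetic_code", 1)),
    )
    tree = read_newick(_require("models", cfg, "tree"))
    families = cfg.get("families", ["M0", "branch2"])
    kwargs = {}
    if "omega_starts" in cfg:
        kwargs["omega_starts"] = [float(x) for x in cfg["omega_starts"]]
    if "frequencies" in cfg:
        kwargs["frequencies"] = cfg["frequencies"]
    fits = fit_model_series(aln, tree, families, **kwargs)
    fit_rows = []
    for name, fit in fits.items():
        fit_rows.append([
            name, f"{fit.lnL:.6f}", fit.n_free_params, fit.converged,
            json.dumps({k: round(v, 6) if isinstance(v, float) else v
                        for k, v in fit.params.items()}, sort_keys=True),
        ])
    _write_tsv(outdir / "model_fits.tsv",
               ["model", "lnL", "n_free_params", "converged", "parameters"],
               fit_rows)
    with open(outdir / "model_fits.json", "w") as fh:
        json.dump(
            {
                name: {
                    "lnL": fit.lnL, "params": fit.params,
                    "n_free_params": fit.n_free_params,
                    "starts": fit.starts,
                }
                for name, fit in fits.items()
            },
            fh, indent=1, sort_keys=True,
        )
    tests = []
    for alt, null in NESTED_PAIRS.items():
        if alt in fits and null in fits:
            tests.append(likelihood_ratio_test(fits[null], fits[alt]))
    if tests:
        adjusted = bh_adjust([t.p_value for t in tests])
        alpha = float(cfg.get("lrt_alpha", 0.05))
        _write_tsv(
            outdir / "lrt_tests.tsv",
            ["null", "alt", "stat", "df", "p_value", "p_adjusted",
             "significant"],
            [
                [t.null, t.alt, f"{t.stat:.6f}", t.df, f"{t.p_value:.6g}",
                 f"{p_adj:.6g}", p_adj <= alpha]
                for t, p_adj in zip(tests, adjusted)
            ],
        )
        return ["model_fits.tsv", "model_fits.json", "lrt_tests.tsv"]
    return ["model_fits.tsv", "model_fits.json"]


def _run_divergence(cfg, outdir: Path, seed: int) -> list[str]:
    aln = read_alignment(_require("divergence", cfg, "alignment"))
    tree = read_newick(_require("divergence", cfg, "tree"))
    result = estimate_type1_divergence(
        aln, tree,
        cluster_a_ids=cfg["cluster_a"], cluster_b_ids=cfg["cluster_b"],
        n_bootstrap=int(cfg.get("n_bootstrap", 500)),
        method=cfg.get("count_method", "expected"),
        seed=seed,
    )
    cutoff, sites = select_divergent_sites(
        result, alpha=float(cfg.get("alpha", 0.05))
    )
    _write_tsv(
        outdir / "divergence.tsv",
        ["theta", "se_theta", "lrt_stat", "p_value", "cutoff",
         "n_selected_sites", "selected_sites"],
        [[f"{result.theta:.6f}", _fmt(result.se_theta),
          f"{result.lrt_stat:.6f}", f"{result.p_value:.6g}",
          _fmt(cutoff), len(sites),
          ",".join(str(s + 1) for s in sites)]],
    )
    _write_tsv(
        outdir / "divergence_posteriors.tsv",
        ["column", "posterior"],
        [[i + 1, f"{p:.6f}"]
         for i, p in enumerate(result.site_posteriors)],
    )
    return ["divergence.tsv", "divergence_posteriors.tsv"]


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def make_demo_config(workdir: str | Path, seed: int = 1) -> PipelineConfig:
    """Generate a small synthetic dataset for every stage and return a
    config that runs the whole pipeline over it (the packaged demo)."""
    from .codonml import CodonFrequencies, CodonModelSpec
    from .core_io import write_fasta, write_newick
    from .homology import DomainHit, write_blast_tab, write_domtblout
    from .simulate import (simulate_codon_alignment,
                           simulate_divergent_clusters, simulate_hit_table,
                           simulate_wgd_gene_orders)

    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    rng_evalues = [1e-40, 1e-25, 5e-3, 0.5]

    # screen inputs
    dom_hits = [
        DomainHit(f"prot{i}", "FAM14", rng_evalues[i % 4],
                  rng_evalues[i % 4], 1, 90, 5, 100, 110)
        for i in range(8)
    ]
    write_domtblout(dom_hits, wd / "hits.domtblout")
    from .core_io import SequenceRecord
    base = "MKVLITGAGSGIGLELARQFAHEGANVILVGRNEEKLRQVADSIREDGGEAIAV"
    seqs = [
        SequenceRecord("seqA", base * 2),
        SequenceRecord("seqA_iso", (base * 2)[:90]),
        SequenceRecord("seqB", base[::-1] * 2),
    ]
    write_fasta(seqs, wd / "proteins.fasta")
    fwd, rev, _ = simulate_hit_table(4, 4, noise_hits=4,
                                     n_forward_decoys=1, seed=seed)
    write_blast_tab(fwd, wd / "forward.tsv")
    write_blast_tab([h for hits in rev.values() for h in hits],
                    wd / "reverse.tsv")

    # synteny inputs
    region_a, region_b, families, _ = simulate_wgd_gene_orders(
        60, retention=0.6, n_inversions=1, seed=seed
    )
    for region, name in ((region_a, "region_a.bed"), (region_b, "region_b.bed")):
        with open(wd / name, "w") as fh:
            for l in region:
                s = l.order_index * 1000
                fh.write(f"{l.chrom}\t{s}\t{s + 500}\t{l.gene_id}\t0\t{l.strand}\n")
    with open(wd / "families.tsv", "w") as fh:
        for fam in families:
            for m in fam.member_ids:
                fh.write(f"{fam.family_id}\t{m}\n")
    from .homology import HitRecord
    out_hits = [
        HitRecord(m, fam.anchor_id, 1e-60, 400.0)
        for fam in families for m in fam.member_ids
    ]
    write_blast_tab(out_hits, wd / "outgroup.tsv")

    # rates + models inputs
    tree = read_newick(
        "((fish1:0.3,fish2:0.3) #1 :0.2,(mam1:0.15,mam2:0.15):0.2);"
    )
    spec = CodonModelSpec.branch2(
        kappa=2.0, omega_bg=0.05, omega_fg=0.4,
        frequencies=CodonFrequencies.uniform(),
    )
    aln, _ = simulate_codon_alignment(tree, spec, n_codons=120, seed=seed)
    write_fasta(aln, wd / "codon_aln.fasta")
    write_newick(tree, wd / "tree.nwk")
    with open(wd / "clades.tsv", "w") as fh:
        fh.write("fish1\tfish\nfish2\tfish\nmam1\tmammal\nmam2\tmammal\n")
    with open(wd / "partitions.tsv", "w") as fh:
        fh.write("Nterm\t1\t40\nCterm\t41\t120\n")

    # divergence inputs
    sub = "(a1:0.4,(a2:0.3,(a3:0.25,a4:0.2):0.1):0.1);"
    tree_a = read_newick(sub)
    tree_b = read_newick(sub.replace("a", "b"))
    paln, _ = simulate_divergent_clusters(tree_a, tree_b, 150, theta=0.5,
                                          seed=seed)
    write_fasta(paln, wd / "divergence_aln.fasta")
    joint = (f"({sub[:-1].rstrip(';')}:0.5,"
             f"{sub.replace('a', 'b')[:-1].rstrip(';')}:0.5);")
    write_newick(read_newick(joint), wd / "divergence_tree.nwk")

    doc = {
        "seed": seed,
        "output_dir": str(wd / "out"),
        "stages": {
            "screen": {
                "domtblout": str(wd / "hits.domtblout"),
                "sequences": str(wd / "proteins.fasta"),
                "forward_hits": str(wd / "forward.tsv"),
                "reverse_hits": str(wd / "reverse.tsv"),
            },
            "synteny": {
                "loci_a": str(wd / "region_a.bed"),
                "loci_b": str(wd / "region_b.bed"),
                "families": str(wd / "families.tsv"),
                "outgroup_hits": str(wd / "outgroup.tsv"),
                "window_size": 100,
                "min_pairs": 3,
            },
            "rates": {
                "codon_alignment": str(wd / "codon_aln.fasta"),
                "clades": str(wd / "clades.tsv"),
                "partitions": str(wd / "partitions.tsv"),
                "reference_id": "fish1",
            },
            "models": {
                "codon_alignment": str(wd / "codon_aln.fasta"),
                "tree": str(wd / "tree.nwk"),
                "families": ["M0", "branch2"],
                "omega_starts": [0.2],
            },
            "divergence": {
                "alignment": str(wd / "divergence_aln.fasta"),
                "tree": str(wd / "divergence_tree.nwk"),
                "cluster_a": ["a1", "a2", "a3", "a4"],
                "cluster_b": ["b1", "b2", "b3", "b4"],
                "n_bootstrap": 50,
            },
        },
    }
    with open(wd / "config.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return PipelineConfig.from_dict(doc)


def run_pipeline(config: PipelineConfig | Mapping[str, Any] | str | Path
                 ) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, Mapping):
        config = PipelineConfig.from_dict(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}}
    log_lines = [f"wgdtrace {__version__}", f"seed={config.seed}"]
    for stage in STAGE_ORDER:
        cfg = config.stages.get(stage)
        if not cfg or not cfg.get("enabled", True):
            continue
        log_lines.append(f"[{stage}] parameters: "
                         + json.dumps(cfg, sort_keys=True, default=str))
        try:
            if stage == "screen":
                outputs = _run_screen(cfg, outdir)
            elif stage == "synteny":
                outputs = _run_synteny(cfg, outdir)
            elif stage == "rates":
                outputs = _run_rates(cfg, outdir)
            elif stage == "models":
                outputs = _run_models(cfg, outdir)
            else:
                outputs = _run_divergence(cfg, outdir, config.seed)
        except PipelineError:
            (outdir / "FAILED").write_text(stage + "\n")
            raise
        except Exception as exc:
            (outdir / "FAILED").write_text(stage + "\n")
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = outputs
        log_lines.append(f"[{stage}] wrote: {', '.join(outputs)}")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
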