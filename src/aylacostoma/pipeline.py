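"""End-to-end analysis pipeline driven by a single YAML config.

Stages: profile -> distances -> NJ tree with bootstrap -> relative rate
test -> barcode-gap partitioning -> K/theta -> net-divergence dating,
writing one table per stage (mirroring the layout of published species-
delimitation studies) plus a provenance log.  All stochastic stages derive
their streams from the single config seed, so a rerun with the same config
produces a byte-identical bundle.  Any stage failure aborts the run and no
partial bundle is left behind (outputs are staged in a temporary directory
and moved into place only on success).
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import shutil
import tempfile
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .alignment_io import (
    collapse_haplotypes,
    composition,
    pairwise_site_diffs,
    read_fasta,
    read_groups,
    variable_positions,
)
from .clock_dating import date_all_splits, tajima_rrt
from .delimitation import AbgdConfig, abgd_scan, ktheta_test
from .distances import distance_matrix
from .nj_tree import bootstrap_support
from .rna_structure import (
    classify_variable_sites,
    parse_dot_bracket,
    write_classification_tsv,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclasses.dataclass
class PipelineConfig:
    alignment: Path
    groups: Path
    outdir: Path
    seed: int
    structure: Path | None = None
    model: str = "k2p"
    deletion: str = "pairwise"
    bootstrap_replicates: int = 1000
    abgd: AbgdConfig = dataclasses.field(default_factory=AbgdConfig)
    theta_policy: str = "max_within"
    thetas: dict[str, float] = dataclasses.field(default_factory=dict)
    rrt: dict[str, str] | None = None  # taxon1/taxon2/outgroup sequence ids
    guide_tree: str | None = None  # Newick over group names, or a file path
    rate_2mu: float = 0.006
    dating_replicates: int = 1000
    raw: dict[str, Any] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def _resolve(p: str | None) -> Path | None:
            return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

        try:
            cfg = cls(
                alignment=_resolve(data["alignment"]),
                groups=_resolve(data["groups"]),
                outdir=_resolve(data["outdir"]),
                seed=int(data["seed"]),
                structure=_resolve(data.get("structure")),
                model=data.get("model", "k2p"),
                deletion=data.get("deletion", "pairwise"),
                bootstrap_replicates=int(data.get("bootstrap_replicates", 1000)),
                abgd=AbgdConfig(**data.get("abgd", {})),
                theta_policy=data.get("ktheta", {}).get("policy", "max_within"),
                thetas={
                    str(k): float(v)
                    for k, v in data.get("ktheta", {}).get("thetas", {}).items()
                },
                rrt=data.get("rrt"),
                guide_tree=data.get("dating", {}).get("guide_tree"),
                rate_2mu=float(data.get("dating", {}).get("rate_2mu", 0.006)),
                dating_replicates=int(data.get("dating", {}).get("replicates", 1000)),
                raw=data,
            )
        except KeyError as exc:
            raise PipelineError(f"config missing required key: {exc}") from exc
        return cfg


def _pair_name(g1: str, g2: str) -> str:
    return "-".join(sorted((g1, g2)))


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage; returns the bundle's output paths."""
    outdir = Path(cfg.outdir)
    staging = Path(tempfile.mkdtemp(prefix="aylacostoma_"))
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "load"
        if not Path(cfg.alignment).exists():
            raise PipelineError(f"alignment file not found: {cfg.alignment}")
        if not Path(cfg.groups).exists():
            raise PipelineError(f"groups file not found: {cfg.groups}")
        aln = read_fasta(cfg.alignment)
        groups = read_groups(cfg.groups)

        stage = "profile"
        prof = staging / "profile.tsv"
        with open(prof, "w") as fh:
            fh.write("section\tkey\tvalue\n")
            var = variable_positions(aln)
            fh.write(f"alignment\tn_sequences\t{len(aln)}\n")
            fh.write(f"alignment\tn_columns\t{aln.length}\n")
            fh.write(f"alignment\tvariable_positions\t{','.join(map(str, var))}\n")
            haps = collapse_haplotypes(aln, groups)
            for grp in groups:
                fh.write(f"haplotypes\t{grp}\t{len(haps[grp])}\n")
            for grp, ids in groups.items():
                comp = composition(aln, ids[0])
                for base in "ACGT":
                    fh.write(
                        f"composition:{grp}\t{base}\t"
                        f"{comp.counts[base]} ({comp.percents[base]:.2f}%)\n"
                    )
                fh.write(f"composition:{grp}\tAT\t{comp.at_content:.2f}%\n")
                fh.write(f"composition:{grp}\tGC\t{comp.gc_content:.2f}%\n")
                fh.write(
                    f"composition:{grp}\tungapped_length\t{comp.ungapped_length}\n"
                )
            for g1, g2 in itertools.combinations(groups, 2):
                s = pairwise_site_diffs(aln, groups[g1][0], groups[g2][0])
                fh.write(
                    f"differences\t{_pair_name(g1, g2)}\t"
                    f"{s.nucleotide_differences} nt, {s.indel_events} indel(s)\n"
                )
        written["profile"] = prof

        stage = "distances"
        dm = distance_matrix(aln, cfg.model, cfg.deletion)
        dm_path = staging / "distances.tsv"
        dm.to_tsv(dm_path)
        written["distances"] = dm_path

        stage = "structure"
        if cfg.structure is not None:
            structure = parse_dot_bracket(
                Path(cfg.structure).read_text(), aln.length
            )
            spath = staging / "structure_classes.tsv"
            write_classification_tsv(classify_variable_sites(aln, structure), spath)
            written["structure"] = spath

        stage = "tree"
        tree = bootstrap_support(
            aln, cfg.model, cfg.bootstrap_replicates, seed=cfg.seed,
            deletion=cfg.deletion,
        )
        tree_path = staging / "tree.nwk"
        tree_path.write_text(tree.to_newick() + "\n")
        written["tree"] = tree_path

        stage = "rrt"
        if cfg.rrt is not None:
            res = tajima_rrt(
                aln, cfg.rrt["taxon1"], cfg.rrt["taxon2"], cfg.rrt["outgroup"]
            )
            rpath = staging / "rrt.tsv"
            with open(rpath, "w") as fh:
                fh.write("taxon1\ttaxon2\toutgroup\tm1\tm2\tchi_square\tp_value\n")
                fh.write(
                    f"{cfg.rrt['taxon1']}\t{cfg.rrt['taxon2']}\t{cfg.rrt['outgroup']}\t"
                    f"{res.m1}\t{res.m2}\t{res.chi_square:.4f}\t{res.p_value:.4f}\n"
                )
            written["rrt"] = rpath

        stage = "abgd"
        scan = abgd_scan(dm, cfg.abgd)
        ppath = staging / "partitions.tsv"
        with open(ppath, "w") as fh:
            fh.write("partition_no\tgroups\tprior\tstable\tmembers\n")
            for k, part in enumerate(scan.partitions, start=1):
                members = ";".join("|".join(g) for g in part.groups)
                fh.write(
                    f"{k}\t{part.n_groups}\t{part.prior:.6f}\t{part.stable}\t{members}\n"
                )
        written["partitions"] = ppath
        hpath = staging / "histogram.csv"
        with open(hpath, "w") as fh:
            fh.write("bin_low,bin_high,count\n")
            for lo, hi, c in zip(
                scan.histogram_bins, scan.histogram_bins[1:], scan.histogram_counts
            ):
                fh.write(f"{lo:.6f},{hi:.6f},{c}\n")
        written["histogram"] = hpath

        stage = "ktheta"
        kpath = staging / "ktheta.tsv"
        with open(kpath, "w") as fh:
            fh.write("clades\ttheta\tK\tratio\tn1\tn2\tpolicy\tdistinct\n")
            for g1, g2 in itertools.combinations(groups, 2):
                name = _pair_name(g1, g2)
                supplied = cfg.thetas.get(name)
                policy = "supplied" if supplied is not None else cfg.theta_policy
                res = ktheta_test(
                    dm, groups[g1], groups[g2], theta_policy=policy,
                    theta=supplied, seq_length=aln.length,
                )
                fh.write(
                    f"{name}\t{res.theta:.7f}\t{res.k:.7f}\t{res.ratio:.2f}\t"
                    f"{res.n1}\t{res.n2}\t{res.theta_policy}\t{res.decision}\n"
                )
        written["ktheta"] = kpath

        stage = "dating"
        if cfg.guide_tree is not None:
            guide = cfg.guide_tree
            guide_path = Path(cfg.guide_tree)
            if guide_path.exists():
                guide = guide_path.read_text()
            rows = date_all_splits(
                aln, groups, guide, cfg.rate_2mu, cfg.dating_replicates,
                seed=cfg.seed,
            )
            dpath = staging / "dating.tsv"
            with open(dpath, "w") as fh:
                fh.write("node\tDa\tSE\trate_2mu\tT_Myr\tci_low\tci_high\n")
                for label, est in rows:
                    fh.write(
                        f"{label}\t{est.da:.7f}\t{est.se:.7f}\t{est.rate_2mu}\t"
                        f"{est.time:.2f}\t{est.ci_low:.2f}\t{est.ci_high:.2f}\n"
                    )
            written["dating"] = dpath

        stage = "log"
        log = {
            "package": "aylacostoma",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.raw,
            "config_hash": hashlib.sha256(
                json.dumps(cfg.raw, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "outputs": sorted(p.name for p in written.values()),
        }
        lpath = staging / "run.json"
        lpath.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
        written["log"] = lpath

        outdir.mkdir(parents=True, exist_ok=True)
        final: dict[str, Path] = {}
        for key, src in written.items():
            dst = outdir / src.name
            shutil.move(str(src), dst)
            final[key] = dst
        return final
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        shutil.rmtree(staging, ignore_errors=True)
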