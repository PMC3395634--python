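"""End-to-end analysis driver: files in, per-site results out.

Composes the three stages — alignment-wide nuisance fit, per-site
MEME/FEL fits, and optional empirical-Bayes branch reports — and handles
partitioned alignments (one tree per recombination-free segment, site
ranges in 1-based codon coordinates).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alignment import CodonAlignment, read_codon_fasta
from .eb import branch_posteriors, evidence_to_json_dict
from .genetic_code import get_genetic_code
from .global_fit import GlobalFit, fit_global_mg94, fit_nucleotide_gtr
from .likelihood import SitePruner
from .phylo import parse_newick, validate_tree_alignment
from .site_tests import (
    DEFAULT_P_THRESHOLD,
    MixtureNull,
    SiteTestResult,
    analyze_sites,
    bh_qvalues,
    results_to_frame,
)

logger = logging.getLogger("memesel")


@dataclass
class Partition:
    start: int  # 1-based inclusive codon coordinates
    end: int
    tree_path: str


@dataclass
class PartitionConfig:
    partitions: list[Partition]

    def validate(self, n_sites: int) -> None:
        spans = sorted((p.start, p.end) for p in self.partitions)
        if spans[0][0] != 1 or spans[-1][1] != n_sites:
            raise ValueError(
                f"partitions must cover sites 1..{n_sites} exactly"
            )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 != e1 + 1:
                raise ValueError(
                    f"partitions must be disjoint and contiguous "
                    f"(gap or overlap between {e1} and {s2})"
                )
        if any(p.start > p.end for p in self.partitions):
            raise ValueError("empty partition range")

    @classmethod
    def from_json_file(cls, path: str | Path) -> "PartitionConfig":
        entries = json.loads(Path(path).read_text())
        return cls(
            partitions=[
                Partition(int(e["start"]), int(e["end"]), str(e["tree"]))
                for e in entries
            ]
        )


@dataclass
class AnalysisOptions:
    p_threshold: float = DEFAULT_P_THRESHOLD
    ebf_threshold: float = 20.0
    seed: int = 0
    code_table: int = 1
    stops_policy: str = "strict"
    mixture: MixtureNull = field(default_factory=MixtureNull)
    run_eb: bool = True
    fel_only: bool = False


@dataclass
class AnalysisResult:
    results: list[SiteTestResult]
    global_fits: list[GlobalFit]
    eb: dict[int, list] = field(default_factory=dict)


def run_meme_analysis(
    alignment_path: str | Path,
    tree_path: str | Path | None = None,
    partitions: PartitionConfig | None = None,
    out_dir: str | Path = "memesel_results",
    options: AnalysisOptions | None = None,
) -> AnalysisResult:
    """Run the full pipeline and write result files to ``out_dir``.

    Outputs per partition a global-fit JSON, plus alignment-wide
    ``results.csv``/``results.json`` (one row per codon site, 1-based)
    and, for MEME-significant sites, ``eb_branches.json``.
    """
    opts = options or AnalysisOptions()
    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = get_genetic_code(opts.code_table)
    aln = read_codon_fasta(alignment_path, code, policy=opts.stops_policy)
    logger.info(
        "loaded alignment: %d sequences, %d codon sites",
        aln.n_sequences, aln.n_sites,
    )
    if partitions is None:
        if tree_path is None:
            raise ValueError("either a tree or a partition config is required")
        partitions = PartitionConfig(
            [Partition(1, aln.n_sites, str(tree_path))]
        )
    partitions.validate(aln.n_sites)

    if opts.fel_only:
        return _run_fel_only(aln, partitions, out, opts)

    all_results: list[SiteTestResult] = []
    gfits: list[GlobalFit] = []
    eb_all: dict[int, list] = {}
    try:
        for k, part in enumerate(partitions.partitions):
            tree = parse_newick(Path(part.tree_path).read_text())
            report = validate_tree_alignment(tree, aln)
            if not report.ok:
                raise ValueError(
                    f"partition {k + 1}: tree/alignment mismatch "
                    f"(missing in alignment: {report.missing_in_alignment}, "
                    f"missing in tree: {report.missing_in_tree})"
                )
            logger.info("partition %d (%d..%d): stage 1 global fit",
                        k + 1, part.start, part.end)
            init = fit_nucleotide_gtr(aln, tree)
            gfit = fit_global_mg94(aln, tree, init=init)
            gfits.append(gfit)
            (out / f"global_fit_partition{k + 1}.json").write_text(
                gfit.to_json()
            )
            logger.info(
                "partition %d: lnL=%.3f omega=%.4f", k + 1, gfit.lnL,
                gfit.omega_global,
            )
            sites = list(range(part.start - 1, part.end))

            def progress(done: int, total: int) -> None:
                if done % 50 == 0 or done == total:
                    logger.info("partition %d: fitted %d/%d site patterns",
                                k + 1, done, total)

            results = analyze_sites(
                aln, gfit, null_mixture=opts.mixture,
                p_threshold=opts.p_threshold, sites=sites, progress=progress,
            )
            all_results.extend(results)

            if opts.run_eb and not opts.fel_only:
                kernel = gfit.kernel()
                for r in results:
                    if r.p_meme <= opts.p_threshold and not r.invariant:
                        pruner = SitePruner(
                            aln.columns[r.site - 1], gfit.tree, kernel
                        )
                        eb_all[r.site] = branch_posteriors(
                            pruner, gfit, r.meme_alt
                        )
    except Exception:
        _flush_results(out, all_results, eb_all, opts, failed=True)
        raise

    # q-values are per alignment: recompute across partitions.
    if all_results:
        q_meme = bh_qvalues([r.p_meme for r in all_results])
        q_fel = bh_qvalues([r.fel.p for r in all_results])
        for r, qm, qf in zip(all_results, q_meme, q_fel):
            r.q_meme = float(qm)
            r.q_fel = float(qf)
    _flush_results(out, all_results, eb_all, opts, failed=False)
    logger.info("finished in %.1f s", time.time() - t_start)
    return AnalysisResult(results=all_results, global_fits=gfits, eb=eb_all)


def _run_fel_only(
    aln: CodonAlignment,
    partitions: PartitionConfig,
    out: Path,
    opts: AnalysisOptions,
) -> AnalysisResult:
    import pandas as pd

    from .site_tests import analyze_sites_fel

    frames = []
    gfits = []
    for k, part in enumerate(partitions.partitions):
        tree = parse_newick(Path(part.tree_path).read_text())
        init = fit_nucleotide_gtr(aln, tree)
        gfit = fit_global_mg94(aln, tree, init=init)
        gfits.append(gfit)
        (out / f"global_fit_partition{k + 1}.json").write_text(gfit.to_json())
        frames.append(
            analyze_sites_fel(
                aln, gfit, p_threshold=opts.p_threshold,
                sites=list(range(part.start - 1, part.end)),
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["q_fel"] = bh_qvalues(df["p_fel"].to_numpy())  # across partitions
    df.to_csv(out / "fel_results.csv", index=False, float_format="%.10g")
    return AnalysisResult(results=[], global_fits=gfits)


def _flush_results(
    out: Path,
    results: list[SiteTestResult],
    eb: dict[int, list],
    opts: AnalysisOptions,
    failed: bool,
) -> None:
    frame = results_to_frame(results)
    frame.to_csv(out / "results.csv", index=False, float_format="%.10g")
    provenance = {
        "version": __version__,
        "seed": opts.seed,
        "p_threshold": opts.p_threshold,
        "mixture_null": [[df, w] for df, w in opts.mixture.components],
        "code_table": opts.code_table,
        "stops_policy": opts.stops_policy,
        "status": "FAILED" if failed else "ok",
    }
    (out / "results.json").write_text(
        json.dumps(
            {"provenance": provenance,
             "sites": frame.to_dict(orient="records")},
            indent=2,
        )
    )
    if eb:
        (out / "eb_branches.json").write_text(
            json.dumps(evidence_to_json_dict(eb), indent=2)
        )
    if failed:
        (out / "FAILED").write_text("analysis did not complete\n")


def ebf_annotated_newick(gfit: GlobalFit, evidence) -> str:
    """Newick string with per-branch EBF comment annotations."""
    by_name = {e.branch_name: e for e in evidence}
    tree = gfit.tree

    def fmt(v: int) -> str:
        name = tree.names[v]
        if tree.is_leaf[v]:
            label = name
        else:
            kids = ",".join(fmt(c) for c in tree.children[v])
            label = f"({kids})"
        if tree.parent[v] >= 0:
            b = tree.branch_of_child(v)
            e = by_name.get(b.name)
            if e is not None and e.ebf is not None:
                label += f"[&ebf={e.ebf:.4g}]"
            label += f":{b.length:.6g}"
        return label

    return fmt(tree.root) + ";"
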