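"""End-to-end replication driver: fixture -> search -> consensus -> mapping.

``run_replication`` executes the whole pipeline on the bundled study matrix
and returns (and optionally writes) a machine-readable report: best length,
counts of shortest trees under both branch-collapse conventions, ensemble
CI/RI under both uninformative-character conventions, the outgroup-rooted
strict consensus, and per-tree character-change tables.  Every number in
the report is recomputable from the trees and matrix it ships with.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .consensus import root_with_outgroup, strict_consensus
from .mapping import acctran_reconstruct, annotation_table
from .matrix import CharacterMatrix, load_study_matrix
from .parsimony import character_diagnostics, ensemble_indices
from .search import SearchConfig, SearchResult, collapse_and_dedupe, heuristic_search
from .tree import PhyloTree

__all__ = ["RunReport", "run_replication"]

logger = logging.getLogger("morphpars")


@dataclass
class RunReport:
    """Structured outcome of a full replication run."""

    n_taxa: int
    n_chars: int
    outgroup: list[str]
    config: dict
    best_length: int
    n_binary_mpts: int
    n_mpts_by_collapse_rule: dict[str, int]
    ci_all: float
    ri_all: float
    ci_informative_only: float
    ri_informative_only: float
    consensus_newick: str
    outgroup_monophyletic: bool
    mpt_newicks: list[str]
    replicates_hitting_best: int
    truncated: bool

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


def run_replication(
    config: SearchConfig | None = None,
    out_dir: str | Path | None = None,
    matrix: CharacterMatrix | None = None,
) -> tuple[RunReport, SearchResult]:
    """Run the full analysis; optionally write report files to ``out_dir``.

    Writes ``report.json``, ``mpts.nwk``, ``consensus.nwk``,
    ``characters.tsv`` and one ``annotations_mpt<i>.tsv`` per shortest tree.
    """
    config = config or SearchConfig()
    if matrix is None:
        matrix = load_study_matrix()
    logger.info(
        "searching %d taxa x %d characters (%d replicates, hold %d, %s)",
        matrix.n_taxa, matrix.n_chars, config.n_replicates, config.hold, config.swap,
    )
    result = heuristic_search(matrix, config)
    logger.info(
        "best length %d, %d binary shortest trees, %d/%d replicates hit it",
        result.best_length, len(result.binary_trees),
        result.replicates_hitting_best, config.n_replicates,
    )

    n_by_rule = {
        rule: len(collapse_and_dedupe(result.binary_trees, matrix, rule))
        for rule in ("min_length_zero", "max_length_zero", "none")
    }

    mpt0 = result.binary_trees[0]
    stats_all = ensemble_indices(mpt0, matrix, include_uninformative=True)
    stats_inf = ensemble_indices(mpt0, matrix, include_uninformative=False)

    consensus = strict_consensus(result.binary_trees)
    rooted_consensus = (
        root_with_outgroup(consensus, matrix.outgroup) if matrix.outgroup else consensus
    )

    report = RunReport(
        n_taxa=matrix.n_taxa,
        n_chars=matrix.n_chars,
        outgroup=list(matrix.outgroup),
        config={
            "n_replicates": config.n_replicates,
            "hold": config.hold,
            "seed": config.seed,
            "swap": config.swap,
            "max_trees": config.max_trees,
            "collapse_rule": config.collapse_rule,
        },
        best_length=result.best_length,
        n_binary_mpts=len(result.binary_trees),
        n_mpts_by_collapse_rule=n_by_rule,
        ci_all=round(stats_all.ci, 6),
        ri_all=round(stats_all.ri, 6),
        ci_informative_only=round(stats_inf.ci, 6),
        ri_informative_only=round(stats_inf.ri, 6),
        consensus_newick=rooted_consensus.to_newick(),
        outgroup_monophyletic=bool(rooted_consensus.outgroup_monophyletic),
        mpt_newicks=[t.to_newick() for t in result.trees],
        replicates_hitting_best=result.replicates_hitting_best,
        truncated=result.truncated,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "mpts.nwk").write_text("".join(nw + "\n" for nw in report.mpt_newicks))
        (out / "consensus.nwk").write_text(report.consensus_newick + "\n")
        character_diagnostics(mpt0, matrix).to_csv(out / "characters.tsv", sep="\t", index=False)
        if matrix.outgroup:
            for i, t in enumerate(result.binary_trees, 1):
                rooted = root_with_outgroup(t, matrix.outgroup)
                recon = acctran_reconstruct(rooted, matrix)
                annotation_table(recon).to_csv(
                    out / f"annotations_mpt{i}.tsv", sep="\t", index=False
                )
        with (out / "search_log.jsonl").open("w") as fh:
            for entry in result.log:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
        logger.info("report written to %s", out)
    return report, result
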