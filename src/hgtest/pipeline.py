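"""End-to-end orchestration of the per-gene transfer test, plus the
power / type-I experiment driver.

The per-gene procedure mirrors the analysis workflow: optional sequence
dereplication and column extraction, unconstrained and monophyly-constrained
ML tree searches, per-site log-likelihoods for both trees, KH and AU tests,
and (when a pair of MCMC traces is supplied) the Bayesian H / AICM decision
rule.  A constraint is "rejected" when both frequentist tests fall below
alpha and, if traces are present, the Bayesian rule is also significant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .bayescmp import MCMCTrace, compare_runs
from .models import SubstitutionModel, parse_model
from .phylik import ProteinAlignment, site_ll_matrix
from .prep import SequenceSet, dereplicate, extract_columns
from .seqsim import Scenario, ScenarioConfig, build_hgt_scenario
from .toptest import DEFAULT_N_REP, DEFAULT_SCALES, topology_tests
from .treeops import MonophylyConstraint, rf_distance, search_ml_tree

__all__ = ["PipelineOptions", "PipelineReport", "run_pipeline", "run_experiment"]

log = logging.getLogger("hgtest")


@dataclass
class PipelineOptions:
    alpha: float = 0.05
    search_mode: str = "nni"  # or "exhaustive"
    n_rep: int = DEFAULT_N_REP
    scales: tuple = DEFAULT_SCALES
    seed: int = 0
    derep_max_identity: float | None = None
    score_window: tuple | None = None  # (min_score, max_score)
    require_both: bool = True  # conjunction of KH and AU below alpha
    two_sided_kh: bool = True


@dataclass
class PipelineReport:
    n_sequences: int
    n_sequences_removed: int
    n_sites_in: int
    n_sites_used: int
    unconstrained_tree: str
    constrained_tree: str
    unconstrained_lnl: float
    constrained_lnl: float
    same_topology: bool
    topology_results: list
    bayes: dict | None
    verdict: str
    alpha: float
    seed: int
    version: str = __version__

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "PipelineReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set, frozenset)):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def run_pipeline(alignment, model, constraint: MonophylyConstraint,
                 options: PipelineOptions | None = None,
                 column_scores=None, traces: tuple | None = None,
                 ) -> PipelineReport:
    """Run the per-gene procedure and return a structured report.

    ``alignment`` is a :class:`ProteinAlignment` or a ``SequenceSet`` of
    aligned records; ``model`` is a :class:`SubstitutionModel` or a model
    spec string; ``traces`` is an optional (unconstrained, constrained)
    pair of :class:`MCMCTrace`.
    """
    opt = options or PipelineOptions()
    if isinstance(model, str):
        model = parse_model(model)

    # --- stage 1: redundancy filter -----------------------------------
    removed = 0
    if isinstance(alignment, SequenceSet):
        seqs = alignment
        if opt.derep_max_identity is not None:
            kept = dereplicate(seqs, opt.derep_max_identity)
            removed = len(seqs) - len(kept)
            log.info("derep: removed %d of %d sequences", removed, len(seqs))
            seqs = kept
        alignment = ProteinAlignment.from_records(seqs.records)
    n_seq = alignment.n_taxa
    n_in = alignment.n_sites

    # --- stage 2: column extraction -----------------------------------
    if column_scores is not None and opt.score_window is not None:
        alignment = extract_columns(alignment, column_scores, *opt.score_window)
        log.info("columns: kept %d of %d", alignment.n_sites, n_in)

    # --- stage 3: tree searches ---------------------------------------
    rng = np.random.default_rng(opt.seed)
    test_seed = int(rng.integers(2**31))
    constr_tree, constr_lnl = search_ml_tree(
        alignment, model, constraint, mode=opt.search_mode)
    log.info("constrained search: lnL %.3f", constr_lnl)
    free_tree, free_lnl = search_ml_tree(
        alignment, model, None, mode=opt.search_mode, start_tree=constr_tree)
    log.info("unconstrained search: lnL %.3f", free_lnl)
    if constr_lnl > free_lnl:  # constrained optimum can never beat the free one
        free_tree, free_lnl = constr_tree, constr_lnl
    same = rf_distance(free_tree, constr_tree) == 0

    # --- stage 4: site likelihoods + topology tests -------------------
    if same:
        results = []
        p_kh = p_au = 1.0
    else:
        m = site_ll_matrix(alignment, [free_tree, constr_tree], model,
                           optimize=False,
                           tree_ids=["unconstrained", "constrained"])
        results = topology_tests(m, scales=opt.scales, n_rep=opt.n_rep,
                                 seed=test_seed, two_sided_kh=opt.two_sided_kh)
        by_id = {r.tree_id: r for r in results}
        p_kh = by_id["constrained"].p_kh
        p_au = by_id["constrained"].p_au

    freq_reject = ((p_kh < opt.alpha and p_au < opt.alpha)
                   if opt.require_both
                   else (p_kh < opt.alpha or p_au < opt.alpha))
    # --- stage 5: Bayesian trace criterion ----------------------------
    bayes = None
    if traces is not None:
        report = compare_runs(traces[0], traces[1], diagnostics=True)
        bayes = report.to_dict()
        verdict = "rejected" if (freq_reject and report.significant
                                 and not same) else "not rejected"
    else:
        verdict = "rejected" if (freq_reject and not same) else "not rejected"

    return PipelineReport(
        n_sequences=n_seq, n_sequences_removed=removed,
        n_sites_in=n_in, n_sites_used=alignment.n_sites,
        unconstrained_tree=free_tree.to_newick(),
        constrained_tree=constr_tree.to_newick(),
        unconstrained_lnl=free_lnl, constrained_lnl=constr_lnl,
        same_topology=same,
        topology_results=[r.to_dict() for r in results],
        bayes=bayes, verdict=verdict, alpha=opt.alpha, seed=opt.seed,
    )


def run_experiment(n_scenarios: int, cfg: ScenarioConfig,
                   seed: int = 0, options: PipelineOptions | None = None,
                   table_path=None):
    """Batch scenario simulation + pipeline runs; reports empirical type-I
    rate (null scenarios) and power (transfer scenarios) against truth."""
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    opt = options or PipelineOptions()
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(ss.spawn(n_scenarios)):
        sub = int(child.generate_state(1)[0] % 2**31)
        cfg_i = ScenarioConfig(**{**asdict(cfg), "seed": sub})
        if cfg.transfer is not None:
            cfg_i.transfer = cfg.transfer
        scen = build_hgt_scenario(cfg_i)
        pipe_opt = PipelineOptions(**{**asdict(opt), "seed": sub})
        report = run_pipeline(scen.alignment, cfg_i.substitution_model(),
                              scen.constraint, pipe_opt)
        rows.append({
            "scenario": i, "seed": sub,
            "constraint_true": scen.constraint_true,
            "verdict": report.verdict,
            "delta_lnl": report.unconstrained_lnl - report.constrained_lnl,
            "same_topology": report.same_topology,
        })
        log.info("scenario %d/%d: truth=%s verdict=%s", i + 1, n_scenarios,
                 scen.constraint_true, report.verdict)
    table = pd.DataFrame(rows)
    rejected = table["verdict"] == "rejected"
    nulls = table["constraint_true"]
    out = {
        "n_scenarios": n_scenarios,
        "type_I_rate": float(rejected[nulls].mean()) if nulls.any() else None,
        "power": float(rejected[~nulls].mean()) if (~nulls).any() else None,
        "table": table,
    }
    if table_path is not None:
        table.to_csv(table_path, sep="\t", index=False)
    return out
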