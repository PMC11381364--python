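"""Orchestration: simulate -> align -> statistics, with stable TSV outputs.

The run configuration is a plain dict (typically loaded from YAML):

.. code-block:: yaml

    simulate:            # generate inputs (omit to analyse existing files)
      n_es: 60
      n_reads: 50000
      planted_eps: [10, 20, 30, 40, 50]
      junction_profile: organizer_like
    inputs:              # used when no `simulate` block is given
      template: template.fasta
      induced: [induced_1.fasta, induced_2.fasta]
      controls: [control_1.fasta, control_2.fasta]
    alpha: 0.05
    total_norm: 100000
    max_es: null
    fisher_sided: greater
    primers: {five_prime: null, three_prime: null}

Every output TSV carries the run-manifest hash in a header comment line.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import time

import pandas as pd

from .calls import (
    SamplePopulation,
    call_read,
    iter_fasta_reads,
    population_from_fasta,
)
from .errors import ConfigError
from .manifest import RunManifest
from .simulate import SimulationConfig, make_experiment
from .stats import (
    DEFAULT_NORM_TOTAL,
    eps_call,
    jl_bin_percentages,
    jl_compare,
    normalize_counts,
    overlap_fisher,
)
from .template import TemplatePair, read_template_fasta

log = logging.getLogger("uindel")


def simulation_config_from_dict(d: dict, seed: int | None = None) -> SimulationConfig:
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("planted_eps", "phenotype_sites", "backbone_weights",
                "insertion_u_range", "deletion_u_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    if seed is not None:
        kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


def call_table(records, pair: TemplatePair) -> pd.DataFrame:
    """Per-read call table: read_id, standard, stop site, JL, fully_edited."""
    rows = []
    for rid, seq, count in records:
        c = call_read(seq, pair, read_id=rid, count=count)
        rows.append(
            {
                "read_id": rid,
                "count": count,
                "standard": c.standard,
                "stop_site": c.stop_site if c.standard else pd.NA,
                "junction_length": c.junction_length if c.standard else pd.NA,
                "fully_edited": c.fully_edited if c.standard else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def _stage(name: str):
    log.info("stage %s", name)
    return time.monotonic()


def _done(name: str, t0: float) -> None:
    log.info("stage %s done in %.1fs", name, time.monotonic() - t0)


def run_all(config: dict, outdir, seed: int | None = None) -> dict:
    """Run the full pipeline and write all declared TSVs under ``outdir``.

    Returns a dict with the in-memory results and output paths.  Raises
    :class:`ConfigError` naming the failing stage on invalid configuration.
    """
    os.makedirs(outdir, exist_ok=True)
    alpha = float(config.get("alpha", 0.05))
    total = float(config.get("total_norm", DEFAULT_NORM_TOTAL))
    max_es = config.get("max_es")
    sided = config.get("fisher_sided", "greater")
    primers = config.get("primers") or {}

    manifest = RunManifest(config=config)
    manifest.strategies = {
        "eps_test": "single_case_t_one_sided",
        "adjustment": "benjamini_hochberg",
        "fisher_sided": sided,
        "jl_bins": "[0],[1,10],[11,20],[21,inf) inclusive",
        "jl_span": "junction length = span from stop site to 5'-most "
                   "non-pre-compatible ES, internal pre-edited ESs included",
    }

    # ----- simulate (optional) ---------------------------------------
    if "simulate" in config:
        t0 = _stage("simulate")
        sim = simulation_config_from_dict(config["simulate"] or {}, seed=seed)
        manifest.seeds["simulation"] = sim.seed
        paths = make_experiment(sim, os.path.join(outdir, "simulated"))
        template_path = paths["template"]
        induced_paths = [p for s, p in paths["samples"].items() if s.startswith("induced")]
        control_paths = [p for s, p in paths["samples"].items() if s.startswith("control")]
        _done("simulate", t0)
    elif "inputs" in config:
        inputs = config["inputs"]
        try:
            template_path = inputs["template"]
            induced_paths = list(inputs["induced"])
            control_paths = list(inputs["controls"])
        except KeyError as e:
            raise ConfigError(f"inputs block missing key {e}") from None
    else:
        raise ConfigError("config needs either a 'simulate' or an 'inputs' block")
    if len(induced_paths) != 2:
        raise ConfigError(
            f"induced condition needs exactly 2 replicates, got {len(induced_paths)}"
        )
    if len(control_paths) < 2:
        raise ConfigError(
            f"control condition needs >= 2 samples, got {len(control_paths)}"
        )
    for p in [template_path] + induced_paths + control_paths:
        if not os.path.exists(p):
            raise ConfigError(f"input file missing: {p}")
        manifest.add_input(p)

    # ----- template --------------------------------------------------
    t0 = _stage("template")
    pair = read_template_fasta(template_path, max_es=max_es)
    manifest.write_tsv(pair.to_frame(), os.path.join(outdir, "template_map.tsv"))
    _done("template", t0)

    # ----- align & aggregate -----------------------------------------
    t0 = _stage("align")
    kwargs = {
        "five_prime_primer": primers.get("five_prime"),
        "three_prime_primer": primers.get("three_prime"),
    }
    induced: list[SamplePopulation] = []
    controls: list[SamplePopulation] = []
    for path, cond, dest in [(p, "induced", induced) for p in induced_paths] + [
        (p, "control", controls) for p in control_paths
    ]:
        pop = population_from_fasta(path, pair, condition=cond, **kwargs)
        normalize_counts(pop, total)
        dest.append(pop)
        manifest.sample_totals[pop.sample_id] = {
            "standard": int(pop.total_standard),
            "nonstandard": int(pop.total_nonstandard),
        }
        calls = call_table(iter_fasta_reads(path), pair)
        manifest.write_tsv(
            calls, os.path.join(outdir, f"read_calls_{pop.sample_id}.tsv")
        )
        hist = pd.DataFrame(
            {"es": range(pair.n_es + 1), "raw_count": pop.stop_counts_raw}
        )
        manifest.write_tsv(
            hist, os.path.join(outdir, f"stop_histogram_{pop.sample_id}.tsv")
        )
    _done("align", t0)

    # ----- EPS calling -----------------------------------------------
    t0 = _stage("eps")
    eps = eps_call(induced, controls, alpha=alpha, total=total)
    manifest.write_tsv(eps.to_frame(), os.path.join(outdir, "eps_results.tsv"))
    _done("eps", t0)

    # ----- replicate-level overlap ------------------------------------
    # With a single experiment the Fisher overlap contrasts the two induced
    # replicates' per-replicate significant sets (a replicate-consistency
    # check); cross-knockdown overlaps use `overlap_fisher` directly.
    t0 = _stage("overlap")
    universe = pair.max_es
    per_rep = [
        {
            int(s)
            for s in eps.stop_sites[
                (eps.p_adj[r] < alpha) & (eps.direction[r] > 0)
            ]
            if 1 <= s <= universe
        }
        for r in range(2)
    ]
    overlap = overlap_fisher(per_rep[0], per_rep[1], universe, alternative=sided)
    manifest.write_tsv(overlap.to_frame(), os.path.join(outdir, "overlap.tsv"))
    _done("overlap", t0)

    # ----- junction lengths ------------------------------------------
    t0 = _stage("junctions")
    jl_pct = pd.concat(
        [
            jl_bin_percentages(p).assign(sample_id=p.sample_id, condition=p.condition)
            for p in induced + controls
        ],
        ignore_index=True,
    )
    manifest.write_tsv(jl_pct, os.path.join(outdir, "jl_percentages.tsv"))
    jl_flags = jl_compare(induced, controls, alpha=alpha)
    manifest.write_tsv(jl_flags, os.path.join(outdir, "jl_flags.tsv"))
    _done("junctions", t0)

    manifest.write(os.path.join(outdir, "manifest.json"))
    return {
        "pair": pair,
        "induced": induced,
        "controls": controls,
        "eps": eps,
        "overlap": overlap,
        "jl_flags": jl_flags,
        "outdir": str(outdir),
    }
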