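"""Synthetic amplicon read populations with known editing ground truth.

The generator emulates the structure of MiSeq amplicon libraries of pan-edited
mitochondrial transcripts: a ~300 nt template pair (fully edited ~60 ES), two
induced-knockdown replicates against several control samples, tens of
thousands of reads per sample, and a mixture of fully pre-edited, partially
edited (with or without junctions), fully edited and nonstandard reads.

Every read is defined by a planted (stop site, junction length) pair: ESs 3'
of the stop carry fully edited U counts, the junction's 5'-terminal ES carries
a U count matching neither template state (so the junction end is exactly
where the caller will see it), interior junction ESs are pre-edited, and
everything 5' of the junction is pre-edited.  Generated templates have no
shared sites, so the planted values are recovered exactly by the caller for
uncorrupted reads.  Knockdown effects are planted as additive stop-probability
mass at chosen ESs; junction-length phenotypes replace the JL-bin distribution
at those sites under induction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calls import JL_BIN_LABELS, SamplePopulation, aggregate_population
from .errors import InconsistentConfig
from .template import TemplatePair, build_template_pair, synthesize

#: (lo, hi) ES spans of the four JL bins; hi=None means "to the 5' end".
_BIN_RANGES = ((0, 0), (1, 10), (11, 20), (21, None))

#: Junction-length bin probabilities, per phenotype, order matches JL_BIN_LABELS.
#: "organizer_like" mimics knockdowns that block editing without junction
#: formation (JL=0 mass up, long junctions down); "resc13_like" mimics
#: knockdowns that promote long mis-edited junctions (JL>20 mass up).
JL_PROFILES = {
    "control": (0.40, 0.30, 0.20, 0.10),
    "organizer_like": (0.70, 0.15, 0.10, 0.05),
    "resc13_like": (0.25, 0.25, 0.20, 0.30),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic knockdown experiment."""

    n_es: int = 60
    seed: int = 0
    # template geometry
    backbone_weights: tuple[float, float, float] = (0.45, 0.20, 0.35)  # A, C, G
    insertion_fraction: float = 0.85  # most editing sites gain Us
    insertion_u_range: tuple[int, int] = (1, 4)  # u_full at insertion sites
    deletion_u_range: tuple[int, int] = (1, 3)  # u_pre at deletion sites
    terminal_u5: int = 2
    terminal_u3: int = 1
    # stop-site distribution
    pre_edited_mass: float = 0.15  # stop site 0 (no canonical editing)
    fully_edited_mass: float = 0.05  # stop site n_es
    # planted sites sit in the 3' two-thirds of the amplicon so that every
    # JL bin (including >20 ES) is attainable at each of them
    planted_eps: tuple[int, ...] = (8, 15, 22, 29, 36)
    planted_baseline: float = 0.02  # stop fraction at planted sites, control
    planted_effect: float = 0.08  # added stop fraction under induction
    # optional explicit stop-site distribution over rows 0..n_es (overrides
    # the mass parameters above; planted effects still apply on top)
    stop_probs: tuple[float, ...] | None = None
    # junction model
    junction_profile: str = "organizer_like"  # induced JL profile at planted sites
    phenotype_sites: tuple[int, ...] | None = None  # default: planted_eps
    # optional explicit JL-bin probabilities (order: 0, 1-10, 11-20, >20)
    control_jl_bin_probs: tuple[float, float, float, float] | None = None
    induced_jl_bin_probs: tuple[float, float, float, float] | None = None
    # read population
    n_reads: int = 50_000
    nonstandard_rate: float = 0.02
    n_induced: int = 2
    n_controls: int = 7

    def __post_init__(self) -> None:
        if self.n_es < 2:
            raise InconsistentConfig("n_es must be >= 2")
        bad = [s for s in self.planted_eps if not 1 <= s <= self.n_es - 1]
        if bad:
            raise InconsistentConfig(
                f"planted ES {bad} outside interior sites 1..{self.n_es - 1}"
            )
        if self.junction_profile not in JL_PROFILES:
            raise InconsistentConfig(
                f"unknown junction profile {self.junction_profile!r}; "
                f"known: {sorted(JL_PROFILES)}"
            )
        if not 0 <= self.nonstandard_rate < 1:
            raise InconsistentConfig("nonstandard_rate must be in [0, 1)")
        interior = (
            self.pre_edited_mass
            + self.fully_edited_mass
            + len(self.planted_eps) * self.planted_baseline
        )
        if interior >= 1:
            raise InconsistentConfig("stop-distribution masses exceed 1")

    @property
    def effective_phenotype_sites(self) -> tuple[int, ...]:
        return self.phenotype_sites if self.phenotype_sites is not None else self.planted_eps


def stop_distribution(config: SimulationConfig, condition: str) -> np.ndarray:
    """Stop-site probabilities over rows 0..n_es for one condition.

    Controls: fixed mass at rows 0 and n_es, the planted baseline at planted
    sites, the remainder uniform over the other interior sites.  Induction
    adds the planted effect at planted sites and rescales only the non-planted
    mass so the planted fraction equals baseline + effect exactly.
    """
    n = config.n_es
    planted = np.array(sorted(set(config.planted_eps)), dtype=int)
    if config.stop_probs is not None:
        dist = np.asarray(config.stop_probs, dtype=float)
        if len(dist) != n + 1:
            raise InconsistentConfig(
                f"stop_probs length {len(dist)} != n_es + 1 = {n + 1}"
            )
        if (dist < 0).any() or dist.sum() <= 0:
            raise InconsistentConfig("stop_probs must be non-negative, sum > 0")
        dist = dist / dist.sum()
    else:
        dist = np.zeros(n + 1)
        dist[0] = config.pre_edited_mass
        dist[n] = config.fully_edited_mass
        interior = np.setdiff1d(np.arange(1, n), planted)
        dist[planted] = config.planted_baseline
        dist[interior] = (1.0 - dist.sum()) / len(interior)
    if condition == "induced" and len(planted):
        new_vals = dist[planted] + config.planted_effect
        old_mass = dist[planted].sum()
        if new_vals.sum() >= 1 or old_mass >= 1:
            raise InconsistentConfig("planted effects exceed total probability")
        scale = (1.0 - new_vals.sum()) / (1.0 - old_mass)
        dist = dist * scale
        dist[planted] = new_vals
    return dist / dist.sum()


def jl_bin_probs(config: SimulationConfig, condition: str, stop: int) -> np.ndarray:
    """JL-bin probabilities at one stop site under one condition.

    The induced profile (named, or the explicit override) applies only at the
    phenotype sites; everywhere else both conditions share the control profile.
    """
    if condition == "induced" and stop in config.effective_phenotype_sites:
        if config.induced_jl_bin_probs is not None:
            return np.asarray(config.induced_jl_bin_probs, dtype=float)
        return np.asarray(JL_PROFILES[config.junction_profile])
    if config.control_jl_bin_probs is not None:
        return np.asarray(config.control_jl_bin_probs, dtype=float)
    return np.asarray(JL_PROFILES["control"])


def make_template(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TemplatePair:
    """Random template pair with >= 1 insertion and >= 1 deletion site.

    Every ES differs between the two states (no shared sites), as in
    pan-edited domains where essentially every site is edited; this also makes
    the generator's planted stop sites exact under the caller's definitions.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_es
    backbone = "".join(
        rng.choice(list("ACG"), size=n + 1, p=np.asarray(config.backbone_weights))
    )
    is_insertion = rng.random(n) < config.insertion_fraction
    # guarantee both classes exist
    if is_insertion.all():
        is_insertion[rng.integers(n)] = False
    if not is_insertion.any():
        is_insertion[rng.integers(n)] = True
    lo_i, hi_i = config.insertion_u_range
    lo_d, hi_d = config.deletion_u_range
    u_pre = np.where(is_insertion, 0, rng.integers(lo_d, hi_d + 1, size=n))
    u_full = np.where(is_insertion, rng.integers(lo_i, hi_i + 1, size=n), 0)
    return TemplatePair(
        backbone=backbone,
        u_pre=u_pre,
        u_full=u_full,
        u5_pre=config.terminal_u5,
        u3_pre=config.terminal_u3,
        u5_full=config.terminal_u5,
        u3_full=config.terminal_u3,
    )


def _noncanonical_u_candidates(pair: TemplatePair, es: int, k: int = 3) -> list[int]:
    """Smallest k U counts at ES ``es`` matching neither template state."""
    up, uf = int(pair.u_pre[es - 1]), int(pair.u_full[es - 1])
    out = []
    c = 0
    while len(out) < k:
        if c != up and c != uf:
            out.append(c)
        c += 1
    return out


def _read_sequence(
    pair: TemplatePair, stop: int, jl: int, u_term: int | None, config: SimulationConfig
) -> str:
    """Sequence of a read with planted stop site and junction length."""
    u = pair.u_pre.copy()
    if stop > 0:
        u[:stop] = pair.u_full[:stop]
    if jl > 0:
        u[stop + jl - 1] = u_term
    return synthesize(pair.backbone, u, config.terminal_u5, config.terminal_u3)


def simulate_sample(
    pair: TemplatePair,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> tuple[list[tuple[str, str, int]], pd.DataFrame]:
    """Draw one replicate's read population.

    Returns ``(records, truth)``: records are ``(read_id, sequence, count)``
    with multiplicities over unique sequences; the truth table lists each
    record's planted stop site, junction length and corruption flag.
    """
    if condition not in ("induced", "control"):
        raise InconsistentConfig(f"unknown condition {condition!r}")
    n = pair.n_es
    if n != config.n_es:
        raise InconsistentConfig("template does not match config geometry")
    dist = stop_distribution(config, condition)
    stop_counts = rng.multinomial(config.n_reads, dist)

    # unique (stop, jl, u_term) -> count
    combos: dict[tuple[int, int, int | None], int] = {}
    for s in np.flatnonzero(stop_counts):
        count = int(stop_counts[s])
        max_l = n - s
        probs = jl_bin_probs(config, condition, int(s)).copy()
        # junctions cannot extend past the 5' end: drop unattainable bins
        for bi, (lo, _hi) in enumerate(_BIN_RANGES):
            if lo > max_l:
                probs[bi] = 0.0
        probs /= probs.sum()
        bin_counts = rng.multinomial(count, probs)
        if bin_counts[0]:
            combos[(int(s), 0, None)] = combos.get((int(s), 0, None), 0) + int(
                bin_counts[0]
            )
        for bi in (1, 2, 3):
            if not bin_counts[bi]:
                continue
            lo, hi = _BIN_RANGES[bi]
            hi = max_l if hi is None else min(hi, max_l)
            lengths = rng.integers(lo, hi + 1, size=int(bin_counts[bi]))
            for jl, jl_count in zip(*np.unique(lengths, return_counts=True)):
                cands = _noncanonical_u_candidates(pair, int(s) + int(jl))
                split = rng.multinomial(int(jl_count), np.full(len(cands), 1 / len(cands)))
                for u_term, c in zip(cands, split):
                    if c:
                        key = (int(s), int(jl), int(u_term))
                        combos[key] = combos.get(key, 0) + int(c)

    records: list[tuple[str, str, int]] = []
    truth_rows: list[dict] = []
    corrupted: dict[tuple[int, int, str], int] = {}  # (combo idx, pos, base) -> count
    keys = sorted(combos, key=lambda k: (k[0], k[1], -1 if k[2] is None else k[2]))
    sequences = [
        _read_sequence(pair, s, jl, ut, config) for (s, jl, ut) in keys
    ]
    # positions of backbone (non-U) characters within each synthesized read
    for i, (key, seq) in enumerate(zip(keys, sequences)):
        count = combos[key]
        n_corrupt = rng.binomial(count, config.nonstandard_rate)
        count -= int(n_corrupt)
        if n_corrupt:
            bb_pos = [p for p, c in enumerate(seq) if c != "U"]
            pos_idx = rng.integers(len(bb_pos), size=int(n_corrupt))
            for p in pos_idx:
                pos = bb_pos[int(p)]
                others = [b for b in "ACGU" if b != seq[pos]]
                base = others[int(rng.integers(len(others)))]
                k = (i, pos, base)
                corrupted[k] = corrupted.get(k, 0) + 1
        if count:
            rid = f"{sample_id}_s{key[0]}_j{key[1]}" + (
                "" if key[2] is None else f"_u{key[2]}"
            )
            records.append((rid, seq, count))
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "read_id": rid,
                    "count": count,
                    "true_stop": key[0],
                    "true_jl": key[1],
                    "corrupted": False,
                }
            )
    for (i, pos, base), count in sorted(corrupted.items()):
        s, jl, _ = keys[i]
        seq = sequences[i]
        mut = seq[:pos] + base + seq[pos + 1:]
        rid = f"{sample_id}_ns{i}_p{pos}{base}"
        records.append((rid, mut, count))
        truth_rows.append(
            {
                "sample_id": sample_id,
                "read_id": rid,
                "count": count,
                "true_stop": s,
                "true_jl": jl,
                "corrupted": True,
            }
        )
    return records, pd.DataFrame(truth_rows)


def truth_tables(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Planted-EPS table and per-condition JL-bin expectation table."""
    ctl = stop_distribution(config, "control")
    ind = stop_distribution(config, "induced")
    eps = pd.DataFrame(
        {
            "es": sorted(set(config.planted_eps)),
            "control_stop_fraction": ctl[sorted(set(config.planted_eps))],
            "induced_stop_fraction": ind[sorted(set(config.planted_eps))],
        }
    )
    eps["effect"] = eps["induced_stop_fraction"] - eps["control_stop_fraction"]
    rows = []
    for cond, profile in (
        ("control", "control"),
        ("induced_at_phenotype_sites", config.junction_profile),
    ):
        for label, p in zip(JL_BIN_LABELS, JL_PROFILES[profile]):
            rows.append({"condition": cond, "jl_bin": label, "probability": p})
    return eps, pd.DataFrame(rows)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[TemplatePair, list[SamplePopulation], list[SamplePopulation], pd.DataFrame]:
    """Generate template and all replicates in memory, aggregated by the caller.

    Returns ``(pair, induced, controls, truth_reads)``; the sample populations
    are produced by running every generated read through the real alignment
    and calling path, not by copying the planted values.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.n_induced + config.n_controls)
    pair = make_template(config, np.random.default_rng(children[0]))
    induced, controls, truths = [], [], []
    for i in range(config.n_induced):
        sid = f"induced_{i + 1}"
        recs, truth = simulate_sample(
            pair, config, "induced", np.random.default_rng(children[1 + i]), sid
        )
        induced.append(
            aggregate_population(recs, pair, sample_id=sid, condition="induced")
        )
        truths.append(truth)
    for i in range(config.n_controls):
        sid = f"control_{i + 1}"
        recs, truth = simulate_sample(
            pair,
            config,
            "control",
            np.random.default_rng(children[1 + config.n_induced + i]),
            sid,
        )
        controls.append(
            aggregate_population(recs, pair, sample_id=sid, condition="control")
        )
        truths.append(truth)
    return pair, induced, controls, pd.concat(truths, ignore_index=True)


def write_fasta(records: list[tuple[str, str, int]], path) -> None:
    """Write ``(read_id, seq, count)`` records with the ``;count=N`` convention."""
    with open(path, "w") as fh:
        for rid, seq, count in records:
            fh.write(f">{rid};count={count}\n{seq}\n")


def make_experiment(config: SimulationConfig, outdir) -> dict:
    """Write a full experiment (template, per-sample FASTAs, truth tables).

    Produces ``template.fasta``, ``induced_*.fasta`` / ``control_*.fasta``,
    ``truth_eps.tsv``, ``truth_jl_bins.tsv`` and ``truth_reads.tsv`` under
    ``outdir`` and returns a manifest-style dict of the paths.
    """
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.n_induced + config.n_controls)
    pair = make_template(config, np.random.default_rng(children[0]))
    template_path = os.path.join(outdir, "template.fasta")
    with open(template_path, "w") as fh:
        fh.write(f">pre_edited\n{pair.pre_edited}\n>fully_edited\n{pair.fully_edited}\n")

    sample_paths: dict[str, str] = {}
    truths = []
    layout = [("induced", i) for i in range(config.n_induced)] + [
        ("control", i) for i in range(config.n_controls)
    ]
    for k, (cond, i) in enumerate(layout):
        sid = f"{cond}_{i + 1}"
        recs, truth = simulate_sample(
            pair, config, cond, np.random.default_rng(children[1 + k]), sid
        )
        path = os.path.join(outdir, f"{sid}.fasta")
        write_fasta(recs, path)
        sample_paths[sid] = path
        truths.append(truth)

    eps_truth, jl_truth = truth_tables(config)
    eps_path = os.path.join(outdir, "truth_eps.tsv")
    jl_path = os.path.join(outdir, "truth_jl_bins.tsv")
    reads_path = os.path.join(outdir, "truth_reads.tsv")
    eps_truth.to_csv(eps_path, sep="\t", index=False)
    jl_truth.to_csv(jl_path, sep="\t", index=False)
    pd.concat(truths, ignore_index=True).to_csv(reads_path, sep="\t", index=False)
    return {
        "template": template_path,
        "samples": sample_paths,
        "truth_eps": eps_path,
        "truth_jl_bins": jl_path,
        "truth_reads": reads_path,
    }
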