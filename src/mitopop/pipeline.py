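"""Config-driven pipeline: diversity -> AMOVA/F_ST -> MDS -> lineage ->
network -> ABC, with a run manifest.

The config is a single YAML document; all randomness is funnelled
through named seeds so that a rerun with the same inputs and config
produces identical outputs (and identical manifest hashes).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

import mitopop
from mitopop.alignment import (
    AlignmentError,
    MetadataError,
    collapse_haplotypes,
    extract_window,
    polymorphic_sites,
    read_alignment,
)
from mitopop.mds import mds_from_fst
from mitopop.mjnet import median_joining, network_summary
from mitopop.nj import assign_lineage, bootstrap_support
from mitopop.popgen import amova, diversity_table, pairwise_fst
from mitopop.abc.modelchoice import model_choice, scenario_choice_error
from mitopop.abc.estimate import estimate_parameters, goodness_of_fit
from mitopop.abc.reftable import build_reference_table
from mitopop.abc.scenario import ScenarioError, parse_priors, parse_scenarios


class ConfigError(ValueError):
    """Invalid configuration (exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (exit code 3)."""


class StageFailure(RuntimeError):
    """A stage failed after earlier stages completed (manifest records it)."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


ALL_STAGES = ("diversity", "amova", "fst", "mds", "lineage", "network", "abc")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}")
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Full up-front validation; returns the requested stage list."""
    stages = cfg.get("stages", list(ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; valid: {list(ALL_STAGES)}")
    inp = cfg.get("input", {})
    needs_alignment = any(s != "abc" for s in stages) or "abc" not in stages
    if needs_alignment:
        for key in ("fasta", "metadata"):
            if key not in inp:
                raise ConfigError(f"input.{key} is required")
            if not Path(inp[key]).exists():
                raise ConfigError(f"input.{key} does not exist: {inp[key]}")
    seeds = cfg.get("seeds", {})
    if cfg.get("permutations", 0) > 0 and ("amova" in stages or "fst" in stages):
        if "permutation" not in seeds:
            raise ConfigError("seeds.permutation required when permutations > 0")
    if "lineage" in stages:
        lin = cfg.get("lineage", {})
        for key in ("refs_fasta", "refs_metadata"):
            if key not in lin:
                raise ConfigError(f"lineage.{key} is required for the lineage stage")
            if not Path(lin[key]).exists():
                raise ConfigError(f"lineage.{key} does not exist: {lin[key]}")
    if "abc" in stages:
        abc_cfg = cfg.get("abc")
        if not abc_cfg:
            raise ConfigError("abc block required when the abc stage is enabled")
        for key in ("scenarios", "priors"):
            if key not in abc_cfg:
                raise ConfigError(f"abc.{key} is required")
            if not Path(abc_cfg[key]).exists():
                raise ConfigError(f"abc.{key} does not exist: {abc_cfg[key]}")
        if "abc" not in seeds:
            raise ConfigError("seeds.abc required for the abc stage")
        if "samples" not in abc_cfg or "L" not in abc_cfg:
            raise ConfigError("abc.samples and abc.L are required")
        if "observed_stats" not in abc_cfg:
            raise ConfigError(
                "abc.observed_stats (TSV of name<TAB>value) is required"
            )
    window = inp.get("window")
    if window is not None and (
        not isinstance(window, (list, tuple)) or len(window) != 2
    ):
        raise ConfigError("input.window must be [start, end] (0-based, half-open)")
    return stages


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute the configured stages and write a manifest.

    Returns the manifest dict; raises StageFailure after recording a
    failing stage (completed outputs are left in place).
    """
    stages = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing_policy = cfg.get("missing_policy", "exclude_site")
    pop_level = cfg.get("pop_level", "breed")
    seeds = cfg.get("seeds", {})
    n_perm = int(cfg.get("permutations", 0))

    manifest: dict[str, Any] = {
        "version": mitopop.__version__,
        "seeds": seeds,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": {},
    }

    inp = cfg.get("input", {})
    aln = None
    if inp.get("fasta"):
        manifest["inputs"][str(inp["fasta"])] = _sha256(Path(inp["fasta"]))
        manifest["inputs"][str(inp["metadata"])] = _sha256(Path(inp["metadata"]))
        try:
            aln = read_alignment(inp["fasta"], inp["metadata"])
        except (AlignmentError, MetadataError) as exc:
            raise DataError(str(exc))
        window = inp.get("window")
        if window is not None:
            aln = extract_window(aln, int(window[0]), int(window[1]))

    fst_result = None

    def record(stage: str, outputs: list[Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {p.name: _sha256(p) for p in outputs},
            **(extra or {}),
        }

    def run_stage(stage: str, fn: Callable[[], None]) -> None:
        try:
            fn()
        except BaseException as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            manifest["failure"] = {"stage": stage, "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise StageFailure(stage, exc)

    def stage_diversity() -> None:
        rows = diversity_table(aln, pop_level, missing_policy)
        ht = collapse_haplotypes(aln, missing_policy, pop_level)
        poly = polymorphic_sites(aln, missing_policy)
        path = outdir / "diversity.tsv"
        with open(path, "w") as fh:
            fh.write("population\tn\thaplotypes\th\tse_h\n")
            for r in rows:
                fh.write(
                    f"{r['population']}\t{r['n']}\t{r['haplotypes']}\t"
                    f"{r['h']:.4f}\t{r['se_h']:.4f}\n"
                )
        ht_path = outdir / "haplotypes.tsv"
        ht.to_tsv(ht_path)
        record(
            "diversity",
            [path, ht_path],
            {"n_haplotypes": ht.k, "n_polymorphic_sites": len(poly)},
        )

    def stage_amova() -> None:
        res = amova(
            aln,
            pop_level,
            groups=cfg.get("groups"),
            n_perm=n_perm,
            seed=seeds.get("permutation"),
            missing_policy=missing_policy,
        )
        path = outdir / "amova.tsv"
        with open(path, "w") as fh:
            fh.write("source\tdf\tsum_of_squares\tvariance\tpercentage\n")
            for r in res.to_rows():
                fh.write(
                    f"{r['source']}\t{r['df']}\t{r['sum_of_squares']:.6f}\t"
                    f"{r['variance']:.6f}\t{r['percentage']:.2f}\n"
                )
        record("amova", [path], {"phi_st": res.phi_st, "p_values": res.p_values})

    def stage_fst() -> None:
        nonlocal fst_result
        fst_result = pairwise_fst(
            aln,
            pop_level,
            n_perm=n_perm,
            seed=seeds.get("permutation"),
            missing_policy=missing_policy,
        )
        path = outdir / "fst.tsv"
        fst_result.to_tsv(path)
        record("fst", [path])

    def stage_mds() -> None:
        nonlocal fst_result
        if fst_result is None:
            fst_result = pairwise_fst(aln, pop_level, missing_policy=missing_policy)
        res = mds_from_fst(fst_result, dims=int(cfg.get("mds_dims", 2)),
                           mode=cfg.get("mds_mode", "classical"),
                           seed=seeds.get("mds"))
        path = outdir / "mds.tsv"
        res.to_tsv(path)
        record("mds", [path], {"stress": res.stress})

    def stage_lineage() -> None:
        lin = cfg["lineage"]
        refs = read_alignment(lin["refs_fasta"], lin["refs_metadata"])
        res = assign_lineage(
            aln, refs, method=lin.get("method", "nj_clade"),
            model=lin.get("model", "p"),
        )
        path = outdir / "lineage.tsv"
        with open(path, "w") as fh:
            fh.write("sample_id\tlineage\tambiguous\n")
            for sid in aln.sample_ids:
                fh.write(
                    f"{sid}\t{res.labels[sid]}\t{int(sid in res.ambiguous)}\n"
                )
        record("lineage", [path], {"proportions": res.proportions()})

    def stage_network() -> None:
        ht = collapse_haplotypes(aln, missing_policy, pop_level)
        net = median_joining(ht, epsilon=int(cfg.get("mj_epsilon", 0)))
        edges = outdir / "network_edges.tsv"
        nodes = outdir / "network_nodes.tsv"
        gml = outdir / "network.gml"
        net.edge_list_tsv(edges)
        net.node_table_tsv(nodes)
        net.to_gml(gml)
        s = network_summary(net)
        record(
            "network",
            [edges, nodes, gml],
            {
                "n_nodes": s.n_nodes,
                "n_medians": s.n_medians,
                "n_singletons": s.n_singletons,
            },
        )

    def stage_abc() -> None:
        abc_cfg = cfg["abc"]
        try:
            scenarios = parse_scenarios(Path(abc_cfg["scenarios"]))
            priors = parse_priors(Path(abc_cfg["priors"]))
        except ScenarioError as exc:
            raise ConfigError(str(exc))
        observed = _read_observed_stats(Path(abc_cfg["observed_stats"]))
        samples = {str(k): int(v) for k, v in abc_cfg["samples"].items()}
        rt = build_reference_table(
            scenarios,
            priors,
            int(abc_cfg.get("n_per_scenario", 1000)),
            samples,
            int(abc_cfg["L"]),
            seed=int(seeds["abc"]),
        )
        rt_path = outdir / "reference_table.tsv"
        rt.to_tsv(rt_path)
        obs_vec = np.array([observed[name] for name in rt.stat_names])
        choice = model_choice(rt, obs_vec, tolerance=float(abc_cfg.get("tolerance", 0.01)))
        if abc_cfg.get("n_error_pods", 0):
            choice.predictive_error = scenario_choice_error(
                scenarios, priors, rt,
                n_test=int(abc_cfg["n_error_pods"]),
                seed=int(seeds["abc"]) + 1,
                tolerance=float(abc_cfg.get("tolerance", 0.01)),
            )
        choice_path = outdir / "model_choice.json"
        with open(choice_path, "w") as fh:
            json.dump(choice.to_json_dict(), fh, indent=2)
        outputs = [rt_path, choice_path]
        if abc_cfg.get("estimate", True):
            est = estimate_parameters(
                rt, choice.winner, obs_vec, priors,
                tolerance=float(abc_cfg.get("tolerance", 0.01)),
            )
            est_path = outdir / "parameter_estimates.json"
            payload = {
                sym: {"median": p.median, "q025": p.q025, "q975": p.q975}
                for sym, p in est.parameters.items()
            }
            if abc_cfg.get("n_gof", 0):
                winner_scen = next(
                    s for s in scenarios if s.scenario_id == choice.winner
                )
                payload["_goodness_of_fit"] = goodness_of_fit(
                    winner_scen, est, obs_vec,
                    n_ppc=int(abc_cfg["n_gof"]),
                    seed=int(seeds["abc"]) + 2,
                    rt=rt, priors=priors,
                )
            with open(est_path, "w") as fh:
                json.dump(payload, fh, indent=2)
            outputs.append(est_path)
        record("abc", outputs, {"winner": choice.winner, "posterior": choice.posterior})

    runners = {
        "diversity": stage_diversity,
        "amova": stage_amova,
        "fst": stage_fst,
        "mds": stage_mds,
        "lineage": stage_lineage,
        "network": stage_network,
        "abc": stage_abc,
    }
    for stage in stages:
        run_stage(stage, runners[stage])
    _write_manifest(manifest, outdir)
    return manifest


def _read_observed_stats(path: Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, value = line.split("\t")
        out[name] = float(value)
    if not out:
        raise DataError(f"no observed statistics in {path}")
    return out


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
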