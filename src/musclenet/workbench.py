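"""I/O, configuration and the end-to-end pipeline driver.

On-disk study layout (plain text, inspectable)::

    study_dir/
      metadata.yaml          # fs, design, channel labels, provenance
      trials/
        sub-000_cond-<label>_trial-00.tsv   # columns = channels, tab separated

The pipeline runs simulate -> preprocess -> coherence / PDC -> unmix ->
metrics -> stats (-> synergies), writing tidy TSV tables plus a manifest
that ties every artifact to the configuration hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coherence as coh
from . import mvar as mv
from . import netmetrics as nm
from . import preprocess as pp
from . import synergy as syn
from . import unmixing as um
from .errors import InvalidParameterError, StudyFormatError
from .groupstats import paired_posthoc, rm_anova
from .study import EmgStudy, EmgTrial, StudyDesign
from .synthetic import (DriveSpec, VarCouplingSpec, generate_common_drive_study,
                        generate_var_envelope_study)

log = logging.getLogger("musclenet")

_TRIAL_RE = re.compile(r"sub-(\d+)_cond-(.+)_trial-(\d+)\.tsv$")


# ---------------------------------------------------------------- study I/O

def write_emg_study(study: EmgStudy, path: str | Path) -> Path:
    """Write a study to the documented plain-text layout."""
    root = Path(path)
    (root / "trials").mkdir(parents=True, exist_ok=True)
    meta = {
        "design": study.design.to_dict(),
        "provenance": study.provenance,
    }
    (root / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    for t in study.trials:
        name = f"sub-{t.subject:03d}_cond-{t.condition}_trial-{t.trial:02d}.tsv"
        header = "\t".join(t.channel_labels)
        np.savetxt(root / "trials" / name, t.samples.T, fmt="%.10e",
                   delimiter="\t", header=header, comments="")
    return root


def read_emg_study(path: str | Path) -> EmgStudy:
    """Read a study directory, validating layout and channel consistency."""
    root = Path(path)
    meta_path = root / "metadata.yaml"
    if not meta_path.exists():
        raise StudyFormatError(f"missing metadata sidecar: {meta_path}")
    try:
        meta = yaml.safe_load(meta_path.read_text())
        design = StudyDesign.from_dict(meta["design"])
    except (KeyError, TypeError, ValueError) as exc:
        raise StudyFormatError(f"invalid metadata in {meta_path}: {exc}") from exc
    study = EmgStudy(design=design, provenance=meta.get("provenance", {}))
    trial_dir = root / "trials"
    if not trial_dir.is_dir():
        raise StudyFormatError(f"missing trials directory: {trial_dir}")
    files = sorted(trial_dir.glob("*.tsv"))
    if not files:
        raise StudyFormatError(f"no trial files in {trial_dir}")
    for f in files:
        m = _TRIAL_RE.search(f.name)
        if not m:
            raise StudyFormatError(f"trial file name not understood: {f.name}")
        subject, condition, trial = int(m.group(1)), m.group(2), int(m.group(3))
        df = pd.read_csv(f, sep="\t")
        if list(df.columns) != list(design.channel_labels):
            missing = set(design.channel_labels) - set(df.columns)
            raise StudyFormatError(
                f"{f.name}: channel columns {list(df.columns)} do not match "
                f"study labels (missing: {sorted(missing) or 'none; order differs'})"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
            raise StudyFormatError(f"{f.name}: non-numeric cells in column(s) {bad}")
        study.add(EmgTrial(samples=arr.T, fs=design.fs,
                           channel_labels=design.channel_labels,
                           subject=subject, condition=condition, trial=trial))
    return study


# ------------------------------------------------------------- configuration

_DEFAULT_STAGES = ("simulate", "preprocess", "coherence", "pdc", "unmix",
                   "metrics", "stats", "synergies")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "musclenet_out"
    input_dir: str | None = None
    design: dict = field(default_factory=dict)
    generator: dict = field(default_factory=lambda: {"kind": "common_drive",
                                                     "drives": []})
    stages: dict = field(default_factory=dict)
    welch: dict = field(default_factory=lambda: {
        "window_s": 1.0, "overlap_s": 0.75, "fmax": 100.0})
    surrogate: dict = field(default_factory=lambda: {
        "enabled": False, "n_surrogates": 200, "alpha": 0.05})
    mvar: dict = field(default_factory=lambda: {
        "order": "auto", "p_max": 30, "extended": False})
    nmf: dict = field(default_factory=lambda: {
        "k": 4, "n_restarts": 10, "tol": 1e-6, "max_iter": 500})
    band: tuple[float, float] = (0.0, 60.0)
    threshold: dict = field(default_factory=lambda: {
        "undirected": 0.30, "directed": 0.15})
    synergy: dict = field(default_factory=lambda: {
        "n_synergies": 4, "variance_target": 0.90,
        "lowpass_hz": 10.0, "fs_out": 100.0})

    def __post_init__(self) -> None:
        enabled = {s: True for s in _DEFAULT_STAGES}
        enabled.update(self.stages)
        unknown = set(enabled) - set(_DEFAULT_STAGES)
        if unknown:
            raise InvalidParameterError(f"unknown pipeline stage(s): {sorted(unknown)}")
        self.stages = enabled
        self.validate()

    def validate(self) -> None:
        st = self.stages
        if not (st["simulate"] or self.input_dir):
            raise InvalidParameterError(
                "either the simulate stage or input_dir must provide data"
            )
        if st["unmix"] and not (st["coherence"] or st["pdc"]):
            raise InvalidParameterError(
                "unmix requires the coherence and/or pdc stage"
            )
        if st["metrics"] and not st["unmix"]:
            raise InvalidParameterError("metrics requires the unmix stage")
        if st["stats"] and not st["metrics"]:
            raise InvalidParameterError("stats requires the metrics stage")
        if (st["coherence"] or st["pdc"] or st["synergies"]) and not st["preprocess"]:
            raise InvalidParameterError(
                "coherence/pdc/synergies require the preprocess stage"
            )
        k = int(self.nmf["k"])
        if k < 1:
            raise InvalidParameterError("nmf.k must be >= 1")
        if not (0 < self.threshold["undirected"] <= 1
                and 0 < self.threshold["directed"] <= 1):
            raise InvalidParameterError("threshold fractions must be in (0, 1]")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return plain({
            "seed": self.seed, "out_dir": self.out_dir,
            "input_dir": self.input_dir, "design": self.design,
            "generator": self.generator, "stages": self.stages,
            "welch": self.welch, "surrogate": self.surrogate,
            "mvar": self.mvar, "nmf": self.nmf, "band": list(self.band),
            "threshold": self.threshold, "synergy": self.synergy,
        })

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config key(s): {sorted(unknown)}")
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def study_design(self) -> StudyDesign:
        if not self.design:
            return StudyDesign()
        d = dict(self.design)
        for key in ("conditions", "channel_labels"):
            if key in d:
                d[key] = tuple(d[key])
        return StudyDesign(**d)


def _stage_seed(master: int, stage: str) -> int:
    idx = _DEFAULT_STAGES.index(stage)
    ss = np.random.SeedSequence(master, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ------------------------------------------------------------------ pipeline

def _spectra_to_frame(spectra: list[coh.ConnectivitySpectra]) -> pd.DataFrame:
    rows = []
    for sp in spectra:
        labels = sp.channel_labels
        for k, (a, b) in enumerate(sp.pairs):
            for fi, f in enumerate(sp.freqs):
                rows.append((sp.subject, sp.condition, labels[a], labels[b],
                             f, sp.values[k, fi]))
    cols = ["subject", "condition",
            "source" if spectra[0].directed else "node_a",
            "target" if spectra[0].directed else "node_b",
            "frequency", "value"]
    return pd.DataFrame(rows, columns=cols)


def _networks_to_frame(networks: list[um.MuscleNetwork]) -> pd.DataFrame:
    from .pairs import directed_pairs, undirected_pairs
    rows = []
    for net in networks:
        prs = (directed_pairs(net.n_nodes) if net.directed
               else undirected_pairs(net.n_nodes))
        for a, b in prs:
            rows.append((net.subject, net.condition, net.component,
                         net.channel_labels[a], net.channel_labels[b],
                         net.adjacency[a, b]))
    return pd.DataFrame(rows, columns=["subject", "condition", "component",
                                       "node_a", "node_b", "weight"])


@dataclass
class PipelineResult:
    """In-memory bundle of everything a pipeline run produced."""

    study: EmgStudy | None = None
    spectra: dict = field(default_factory=dict)        # kind -> list[ConnectivitySpectra]
    thresholds: dict = field(default_factory=dict)     # kind -> SurrogateThreshold
    factorizations: dict = field(default_factory=dict) # kind -> NmfFactorization
    stacks: dict = field(default_factory=dict)         # kind -> SpectraStack
    networks: dict = field(default_factory=dict)       # kind -> list[MuscleNetwork]
    metrics: dict = field(default_factory=dict)        # kind -> DataFrame
    anova: dict = field(default_factory=dict)          # (kind, metric) -> AnovaResult
    posthoc: dict = field(default_factory=dict)        # (kind, metric) -> DataFrame
    synergies: list = field(default_factory=list)
    synergy_consistency: np.ndarray | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 study: EmgStudy | None = None) -> PipelineResult:
    """Execute the enabled stages in dependency order.

    A pre-supplied ``study`` overrides the simulate/read stage.  All
    randomness derives from ``config.seed`` through documented substreams,
    so identical configurations give identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()
    artifacts: list[str] = []
    st = config.stages

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        artifacts.append(name)

    def timed(stage):
        t0 = time.perf_counter()
        return lambda: log.info("stage %-10s done in %.2f s", stage,
                                time.perf_counter() - t0)

    # -- data -----------------------------------------------------------
    if study is None:
        done = timed("simulate")
        if st["simulate"]:
            design = config.study_design()
            gen = config.generator
            seed = _stage_seed(config.seed, "simulate")
            if gen.get("kind") == "common_drive":
                drives = [DriveSpec.from_dict(d) for d in gen.get("drives", [])]
                study = generate_common_drive_study(design, drives, seed=seed)
            elif gen.get("kind") == "var_envelope":
                coupling = VarCouplingSpec(
                    coefficients=np.asarray(gen["coefficients"], dtype=float),
                    noise_cov=np.asarray(gen["noise_cov"], dtype=float),
                    mod_depth=float(gen.get("mod_depth", 0.6)),
                    fs_mod=float(gen.get("fs_mod", 200.0)))
                study, _ = generate_var_envelope_study(design, coupling, seed=seed)
            else:
                raise InvalidParameterError(
                    f"unknown generator kind {gen.get('kind')!r}"
                )
        else:
            study = read_emg_study(config.input_dir)
        done()
    res.study = study
    design = study.design

    # -- preprocess -----------------------------------------------------
    envelopes: dict[tuple[int, str], list[pp.EnvelopeTrial]] = {}
    conditioned: dict[tuple[int, str], list[pp.EnvelopeTrial]] = {}
    if st["preprocess"]:
        done = timed("preprocess")
        for s, c, cell in study.iter_cells():
            env = [pp.highpass_rectify(t) for t in cell]
            envelopes[(s, c)] = env
            if st["pdc"]:
                conditioned[(s, c)] = [pp.condition_for_mvar(e) for e in env]
            log.debug("preprocessed subject %s condition %s (%d trials)",
                      s, c, len(cell))
        done()

    # -- coherence ------------------------------------------------------
    if st["coherence"]:
        done = timed("coherence")
        w = config.welch
        und = []
        for (s, c), env in envelopes.items():
            trials = [coh.welch_coherency(e, window_s=w["window_s"],
                                          overlap_s=w["overlap_s"],
                                          fmax=w.get("fmax"))
                      for e in env]
            und.append(coh.pool_coherence(trials))
        res.spectra["undirected"] = und
        save(_spectra_to_frame(und), "spectra_undirected.tsv")
        if config.surrogate.get("enabled"):
            first_cell = next(iter(envelopes.values()))
            res.thresholds["undirected"] = coh.surrogate_threshold(
                first_cell, n_surrogates=int(config.surrogate["n_surrogates"]),
                alpha=float(config.surrogate["alpha"]),
                seed=_stage_seed(config.seed, "coherence"),
                window_s=w["window_s"], overlap_s=w["overlap_s"],
                fmax=w.get("fmax"))
        done()

    # -- pdc ------------------------------------------------------------
    if st["pdc"]:
        done = timed("pdc")
        mv_cfg = config.mvar
        dirsp = []
        for (s, c), cond_trials in conditioned.items():
            pdcs = []
            for trial in cond_trials:
                pdc, model = mv.fit_trial_pdc(
                    trial, order=mv_cfg["order"], p_max=int(mv_cfg["p_max"]),
                    extended=bool(mv_cfg["extended"]))
                pdcs.append(pdc)
                log.debug("fitted MVAR order %d for subject %s %s trial %d",
                          model.order, s, c, trial.trial)
            dirsp.append(mv.pool_pdc(pdcs))
        res.spectra["directed"] = dirsp
        save(_spectra_to_frame(dirsp), "spectra_directed.tsv")
        done()

    # -- unmix / metrics / stats ---------------------------------------
    if st["unmix"]:
        done = timed("unmix")
        for kind, spectra in res.spectra.items():
            stack = um.stack_spectra(spectra, band=config.band)
            fact = um.nmf_als(stack.V, K=int(config.nmf["k"]),
                              tol=float(config.nmf["tol"]),
                              max_iter=int(config.nmf["max_iter"]),
                              n_restarts=int(config.nmf["n_restarts"]),
                              seed=_stage_seed(config.seed, "unmix"))
            fact.freqs = stack.freqs
            fact = um.order_and_normalize(fact)
            res.stacks[kind] = stack
            res.factorizations[kind] = fact
            basis = pd.DataFrame(fact.W, columns=[f"comp{k}" for k in range(fact.K)])
            basis.insert(0, "frequency", stack.freqs)
            save(basis, f"nmf_basis_{kind}.tsv")
            loadings = stack.index.copy()
            for k in range(fact.K):
                loadings[f"comp{k}"] = fact.H[k]
            save(loadings, f"nmf_loadings_{kind}.tsv")
            res.networks[kind] = um.component_networks(fact, stack)
            save(_networks_to_frame(res.networks[kind]), f"networks_{kind}.tsv")
        done()

    if st["metrics"]:
        done = timed("metrics")
        for kind, networks in res.networks.items():
            table = nm.metrics_table(networks)
            res.metrics[kind] = table
            save(table, f"metrics_{kind}.tsv")
        done()

    if st["stats"]:
        done = timed("stats")
        for kind, table in res.metrics.items():
            n_cond = table["condition"].nunique()
            n_comp = table["component"].nunique()
            n_subj = table["subject"].nunique()
            if n_subj < 3 or n_cond < 2 or n_comp < 2:
                log.info("skipping rmANOVA for %s networks: design too small "
                         "(%d subjects, %d conditions, %d components)",
                         kind, n_subj, n_cond, n_comp)
                continue
            frames = []
            for metric in ("CC", "GE", "BC"):
                result = rm_anova(table, dv=metric)
                res.anova[(kind, metric)] = result
                frame = result.to_frame()
                frame.insert(0, "metric", metric)
                frames.append(frame)
                res.posthoc[(kind, metric)] = paired_posthoc(
                    table, effect="condition", dv=metric)
            save(pd.concat(frames, ignore_index=True), f"anova_{kind}.tsv")
            post = pd.concat(
                [res.posthoc[(kind, m)].assign(metric=m) for m in ("CC", "GE", "BC")],
                ignore_index=True)
            save(post, f"posthoc_{kind}.tsv")
        done()

    # -- synergies ------------------------------------------------------
    if st["synergies"]:
        done = timed("synergies")
        sy = config.synergy
        seed = _stage_seed(config.seed, "synergies")
        sets, est_rows = [], []
        for i, ((s, c), env) in enumerate(sorted(envelopes.items())):
            mat = np.concatenate(
                [syn.condition_envelopes_for_synergy(
                    e, lowpass_hz=float(sy["lowpass_hz"]),
                    fs_out=float(sy["fs_out"])) for e in env], axis=1)
            n_est, _ = syn.estimate_n_synergies(
                mat, variance_target=float(sy["variance_target"]))
            est_rows.append({"subject": s, "condition": c,
                             "n_estimated": n_est})
            sets.append(syn.extract_synergies(
                mat, n_synergies=int(sy["n_synergies"]), seed=seed + i,
                subject=s, condition=c))
        if sets:
            aligned, r = syn.align_synergies(sets, sets[0])
            res.synergies = aligned
            res.synergy_consistency = r
            rows = []
            for sset in aligned:
                for k in range(sset.n_synergies):
                    for mi, label in enumerate(design.channel_labels):
                        rows.append({"subject": sset.subject,
                                     "condition": sset.condition,
                                     "synergy": k, "muscle": label,
                                     "weight": sset.basis[k, mi]})
            save(pd.DataFrame(rows), "synergy_basis.tsv")
            save(pd.DataFrame({"synergy": np.arange(len(r)),
                               "consistency_r": r}), "synergy_consistency.tsv")
            save(pd.DataFrame(est_rows), "synergy_count_estimates.tsv")
        done()

    res.manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {k: v for k, v in st.items()},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=2))
    return res


def export_graphml(networks: list[um.MuscleNetwork], out_dir: str | Path) -> list[Path]:
    """Write each network as GraphML (node labels = muscles)."""
    import networkx as nx
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for net in networks:
        G: nx.Graph | nx.DiGraph = nx.DiGraph() if net.directed else nx.Graph()
        for i, lbl in enumerate(net.channel_labels):
            G.add_node(lbl)
        n = net.n_nodes
        for a in range(n):
            for b in range(n):
                if a != b and net.adjacency[a, b] > 0:
                    if not net.directed and a > b:
                        continue
                    G.add_edge(net.channel_labels[a], net.channel_labels[b],
                               weight=float(net.adjacency[a, b]))
        name = (f"network_{'dir' if net.directed else 'und'}_comp{net.component}"
                f"_sub{net.subject:03d}_{net.condition}.graphml")
        nx.write_graphml(G, out / name)
        paths.append(out / name)
    return paths
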