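"""End-to-end pipeline orchestration with a reproducible run manifest.

``run_pipeline`` executes the stages in dependency order — synthetic
fixtures, hypothesis generation, decoy validation, screening + threshold
selection, diversity clustering, pose-contact analysis, pore profiling —
writing diffable CSV/JSON tables plus a manifest recording the config hash,
seeds, input checksums and per-stage row counts.  Re-running an identical
config reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, contacts, hypotheses, pore, screening, synth, validation


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All numeric knobs of the pipeline, with the study-design defaults."""

    seed: int = 0
    # hypothesis generation
    min_features: int = 3
    max_features: int = 5
    min_coverage: float = 0.5
    tolerance: float = 1.0
    max_hypotheses: int = 10
    # screening
    rmsd_max: float = 1.0
    top_n: int = 5000
    min_hypotheses: int = 2
    # synthetic study conditions
    sigma: float = 0.2
    n_actives: int = 6
    decoys_per_active: int = 40
    # clustering
    cluster_threshold: float = 0.75
    min_cluster_size: int = 3
    # contacts / pore
    contact_cutoff: float = 5.0
    contact_high: float = 0.5
    pore_step: float = 0.5
    # stage toggles
    stages: tuple[str, ...] = (
        "synth", "hypo", "validate", "screen", "cluster", "contacts", "pore"
    )

    def __post_init__(self):
        if not (0 < self.min_coverage <= 1):
            raise ConfigError("min_coverage must lie in (0, 1]")
        if self.min_features > self.max_features:
            raise ConfigError("min_features > max_features")
        if self.top_n <= 0 or self.rmsd_max <= 0 or self.tolerance <= 0:
            raise ConfigError("top_n, rmsd_max and tolerance must be positive")
        if not (0 < self.cluster_threshold <= 1):
            raise ConfigError("cluster_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


# a small built-in demo hit list for the clustering stage: amine + aromatic
# chemotypes (blocker-like) alongside structurally distinct fillers
DEMO_HITS = [
    ("hit-01", "CCN(CC)Cc1ccccc1"),
    ("hit-02", "CCN(C)Cc1ccccc1"),
    ("hit-03", "CN(C)Cc1ccccc1O"),
    ("hit-04", "CCN(CC)Cc1ccc(F)cc1"),
    ("hit-05", "C1CCNCC1"),
    ("hit-06", "C1CCN(Cc2ccccc2)CC1"),
    ("hit-07", "OC1CCNC1"),
    ("hit-08", "c1ccc2[nH]ccc2c1"),
    ("hit-09", "Cc1ccc2[nH]ccc2c1"),
    ("hit-10", "c1ccc2occc2c1"),
    ("hit-11", "CCCCCCCC"),
    ("hit-12", "CCCCCCCCO"),
    ("hit-13", "CC(C)CC(C)(C)C"),
    ("hit-14", "OCC(O)C(O)CO"),
    ("hit-15", "NCCc1ccc(O)c(O)c1"),
    ("hit-16", "NCCc1c[nH]c2ccccc12"),
]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _score_library(
    library, hypos, rmsd_max: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-form (molecule, hypothesis) rmsd/score rows for matched pairs."""
    rmsd_rows, score_rows = [], []
    for fs in library:
        for h in hypos:
            m = screening.match_to_hypothesis(fs, h, rmsd_max=rmsd_max)
            if m is not None:
                rmsd_rows.append(
                    {"molecule_id": fs.molecule_id, "hypothesis_id": h.id, "rmsd": m.rmsd}
                )
                score_rows.append(
                    {
                        "molecule_id": fs.molecule_id,
                        "hypothesis_id": h.id,
                        "score": m.screen_score,
                    }
                )
    cols_r = ["molecule_id", "hypothesis_id", "rmsd"]
    cols_s = ["molecule_id", "hypothesis_id", "score"]
    return (
        pd.DataFrame(rmsd_rows, columns=cols_r),
        pd.DataFrame(score_rows, columns=cols_s),
    )


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Run all enabled stages; return the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def done(stage: str, rows: int, files: dict[str, Path]):
        manifest["stages"][stage] = {"status": "ok", "rows": rows}
        for name, p in files.items():
            manifest["outputs"][name] = _checksum(p)

    try:
        if "synth" in cfg.stages:
            spec = synth.PlantedSpec(
                sigma=cfg.sigma,
                n_actives=cfg.n_actives,
                n_decoys_per_active=cfg.decoys_per_active,
                seed=cfg.seed,
            )
            actives, decoys, truth = synth.gen_planted_set(spec)
            state.update(actives=actives, decoys=decoys, truth=truth)
            done("synth", len(actives) + len(decoys), {})

        if "hypo" in cfg.stages:
            hypos = hypotheses.generate_hypotheses(
                state["actives"],
                min_features=cfg.min_features,
                max_features=cfg.max_features,
                min_coverage=cfg.min_coverage,
                tolerance=cfg.tolerance,
                max_hypotheses=cfg.max_hypotheses,
            )
            state["hypos"] = hypos
            hpath = out / "hypotheses.json"
            hypotheses.save_hypotheses(hypos, hpath)
            report = pd.DataFrame(
                [
                    {
                        "id": h.id,
                        "signature": h.signature,
                        "n_matching": int(round(h.coverage * cfg.n_actives)),
                        "hypo_score": round(h.hypo_score, 4),
                    }
                    for h in hypos
                ]
            )
            rpath = out / "hypotheses.csv"
            report.to_csv(rpath, index=False)
            done("hypo", len(hypos), {"hypotheses.json": hpath, "hypotheses.csv": rpath})

        if "validate" in cfg.stages:
            rows = []
            for h in state["hypos"]:
                a_scores, d_scores = [], []
                for fs, sink in [(a, a_scores) for a in state["actives"]] + [
                    (d, d_scores) for d in state["decoys"]
                ]:
                    m = screening.match_to_hypothesis(fs, h, rmsd_max=cfg.rmsd_max)
                    sink.append(0.0 if m is None else m.screen_score)
                auc = validation.roc_auc(a_scores, d_scores)
                counts = validation.counts_from_scores(a_scores, d_scores, 1e-9)
                row = {"hypothesis_id": h.id, "AUC": round(auc, 4)}
                row.update(
                    {k: round(v, 4) for k, v in validation.gh_metrics(counts).items()}
                )
                row["quality"] = validation.classify_model_quality(row["GH"])
                rows.append(row)
            vpath = out / "validation.csv"
            pd.DataFrame(rows).to_csv(vpath, index=False)
            done("validate", len(rows), {"validation.csv": vpath})

        if "screen" in cfg.stages:
            library = state["actives"] + state["decoys"]
            rmsds, scores = _score_library(library, state["hypos"], cfg.rmsd_max)
            passing = screening.first_pass_filter(
                rmsds, top_n=cfg.top_n, min_hypotheses=cfg.min_hypotheses
            )
            scores = scores[scores["molecule_id"].isin(passing)]
            sm = screening.aggregate_tpss(scores)
            d_t, selected = screening.docking_threshold(sm)
            frame = sm.to_frame()
            spath = out / "screen.csv"
            frame.to_csv(spath)
            (out / "screen.log").write_text(
                f"n={len(sm.tpss)} mean_tpss={sm.mean_tpss:.6f} "
                f"sd_tpss={sm.sd_tpss:.6f} d_threshold={d_t:.6f} "
                f"selected={len(selected)}\n"
            )
            state["screen"] = sm
            done("screen", len(frame), {"screen.csv": spath})

        if "cluster" in cfg.stages:
            fps = clustering.fingerprints_from_smiles(DEMO_HITS)
            sim = clustering.tanimoto_matrix(fps)
            ca = clustering.cluster_cut(1.0 - sim, cfg.cluster_threshold)
            rng = np.random.default_rng(cfg.seed + 7)
            ids = [cid for cid, _ in DEMO_HITS]
            energies = clustering.EnergyTable(
                pd.DataFrame(
                    {
                        "dg_no_lipid": np.round(rng.normal(-40, 8, len(ids)), 2),
                        "dg_lipid": np.round(rng.normal(-35, 10, len(ids)), 2),
                    },
                    index=ids,
                )
            )
            reps = clustering.select_representatives(
                ca, energies, min_cluster_size=cfg.min_cluster_size
            )
            table = energies.frame.copy()
            table.insert(0, "cluster", [ca.labels[i] for i in ids])
            table["selected"] = [i in set(reps["id"]) for i in ids]
            cpath = out / "clusters.csv"
            table.to_csv(cpath, index_label="id")
            done("cluster", len(table), {"clusters.csv": cpath})

        if "contacts" in cfg.stages:
            ps, _ = synth.gen_toy_poseset(12, 8, seed=cfg.seed + 11)
            profile = contacts.contact_frequency(ps, cutoff=cfg.contact_cutoff)
            kpath = out / "contacts.csv"
            profile.frame.to_csv(kpath, index=False)
            done("contacts", len(profile.frame), {"contacts.csv": kpath})

        if "pore" in cfg.stages:
            rings = [(float(z), 3.0 if z == 0 else 5.0) for z in range(-10, 11)]
            tp = synth.gen_toy_pore(rings, seed=cfg.seed + 13)
            prof = pore.profile_pore(
                tp.coords, tp.elements, vdw_table=tp.vdw_table,
                z_range=(-8.0, 8.0), step=cfg.pore_step, seed=cfg.seed + 17,
            )
            ppath = out / "pore.csv"
            prof.to_frame().round(4).to_csv(ppath, index=False)
            zones = pore.zone_boundaries_from_profile(prof)
            zpath = out / "zones.json"
            zpath.write_text(json.dumps({k: list(v) for k, v in zones.items()}, indent=1))
            done("pore", len(prof.z), {"pore.csv": ppath, "zones.json": zpath})
    except Exception as exc:
        stage = next(
            (s for s in cfg.stages if s not in manifest["stages"]), "unknown"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
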