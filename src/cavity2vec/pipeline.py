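"""End-to-end pipeline: synth -> encode -> train -> embed -> analyse.

A single hierarchical config (YAML on disk, plain dict in memory) drives
every stage; unknown keys are rejected before anything runs, the
effective config is dumped next to the outputs, and all randomness flows
from one global seed through per-stage derived seeds.  Re-running with
the same config reproduces every artifact bit-for-bit; the manifest
records a SHA-256 per artifact to make that checkable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import analysis, embedding, io as c2v_io, skipgram, synthetic
from .encoding import encode_records
from .errors import Cavity2VecError, PipelineError

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "cavity2vec_run",
    "synth": {
        "enabled": True,
        "k_templates": 3,
        "n_per_template": 50,
        "node_dropout_prob": 0.1,
        "node_swap_prob": 0.05,
        "n_atoms": 400,
        "box": [40.0, 40.0, 40.0],
        "length_range": [10, 40],
        "spacing": 1.5,
        "search_radius": 10.0,
    },
    "encode": {
        "mode": "center",
        "pdb": None,       # external inputs when synth is disabled
        "cavities": None,
    },
    "train": {
        "dimension": 128,
        "window": 5,
        "epochs": 15,
        "negative": 5,
        "min_count": 1,
        "start_lr": 0.025,
        "end_lr": 0.0001,
    },
    "embed": {
        "oov_policy": "skip",
        "normalize": False,
    },
    "cluster": {
        "enabled": True,
        "method": "kmeans",  # or "hierarchical"
        "k": 3,
        "n_init": 10,
        "distance_threshold": None,
    },
    "project": {
        "enabled": True,
        "perplexity": 30.0,
    },
    "profile": {
        "enabled": True,
    },
}


def _merge_strict(defaults: Mapping, overrides: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            raise PipelineError("config", f"unknown config key '{where}'")
        if isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _merge_strict(out[key], value, where)
        else:
            out[key] = value
    return out


def load_config(source: str | Path | Mapping | None = None) -> dict:
    """Resolve a config against the defaults, rejecting unknown keys."""
    if source is None:
        overrides: Mapping = {}
    elif isinstance(source, Mapping):
        overrides = source
    else:
        with open(source) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, Mapping):
            raise PipelineError("config", f"config file {source} is not a mapping")
    return _merge_strict(DEFAULT_CONFIG, overrides)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("synth", "train", "cluster", "project")
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s % 2**31) for n, s in zip(names, state)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: str | Path | Mapping | None = None,
                 out_dir: str | Path | None = None) -> Path:
    """Run every enabled stage; returns the artifact directory.

    Artifacts: atoms.pdb, cavities.jsonl, corpus.txt, labels.tsv (synth),
    embeddings.txt, cavity_vectors.txt, clusters.tsv, tsne.tsv,
    length_width.tsv, amino_acids.tsv, effective_config.yaml and
    manifest.json.
    """
    cfg = load_config(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    artifacts: dict[str, Path] = {}

    def _run(stage: str, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except (Cavity2VecError, ValueError, KeyError, OSError) as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- synth / inputs ----------------------------------------------------
    if cfg["synth"]["enabled"]:
        def _synth():
            s = cfg["synth"]
            ds = synthetic.generate_trajectories(
                k_templates=s["k_templates"],
                n_per_template=s["n_per_template"],
                node_dropout_prob=s["node_dropout_prob"],
                node_swap_prob=s["node_swap_prob"],
                seed=seeds["synth"],
                n_atoms=s["n_atoms"],
                box=s["box"],
                length_range=tuple(s["length_range"]),
                spacing=s["spacing"],
                search_radius=s["search_radius"],
                mode=cfg["encode"]["mode"],
            )
            artifacts.update(ds.write(out))
            return ds
        dataset = _run("synth", _synth)
        atoms = dataset.atoms
        sequences = dataset.sequences
    else:
        def _load():
            enc = cfg["encode"]
            if not enc["pdb"] or not enc["cavities"]:
                raise ValueError("synth disabled: encode.pdb and encode.cavities required")
            atoms = c2v_io.read_pdb(enc["pdb"])
            records = c2v_io.read_cavity_records(enc["cavities"])
            seqs = encode_records(records, atoms, mode=enc["mode"])
            c2v_io.write_corpus(seqs, out / "corpus.txt")
            artifacts["corpus"] = out / "corpus.txt"
            return atoms, seqs
        atoms, sequences = _run("encode", _load)

    # -- train -------------------------------------------------------------
    def _train():
        t = cfg["train"]
        model = skipgram.train(
            [s.tokens for s in sequences],
            skipgram.TrainConfig(
                dimension=t["dimension"], window=t["window"], epochs=t["epochs"],
                negative=t["negative"], min_count=t["min_count"],
                start_lr=t["start_lr"], end_lr=t["end_lr"], seed=seeds["train"],
            ),
        )
        c2v_io.write_embeddings(model, out / "embeddings.txt")
        artifacts["embeddings"] = out / "embeddings.txt"
        return model
    model = _run("train", _train)

    # -- embed -------------------------------------------------------------
    def _embed():
        vecs = embedding.embed_corpus(
            sequences, model,
            oov_policy=cfg["embed"]["oov_policy"],
            normalize=cfg["embed"]["normalize"],
        )
        c2v_io.write_embeddings({v.cavity_id: v.vector for v in vecs},
                                out / "cavity_vectors.txt")
        artifacts["cavity_vectors"] = out / "cavity_vectors.txt"
        return vecs
    vectors = _run("embed", _embed)

    # -- cluster -----------------------------------------------------------
    if cfg["cluster"]["enabled"]:
        def _cluster():
            c = cfg["cluster"]
            if c["method"] == "kmeans":
                asg = analysis.kmeans_cluster(vectors, k=c["k"],
                                              seed=seeds["cluster"], n_init=c["n_init"])
            elif c["method"] == "hierarchical":
                if c["distance_threshold"] is not None:
                    asg = analysis.hierarchical_cluster(
                        vectors, distance_threshold=c["distance_threshold"])
                else:
                    asg = analysis.hierarchical_cluster(vectors, n_clusters=c["k"])
            else:
                raise ValueError(f"unknown clustering method '{c['method']}'")
            with open(out / "clusters.tsv", "w") as fh:
                for cid, lab in asg.assignments.items():
                    fh.write(f"{cid}\t{lab}\n")
            artifacts["clusters"] = out / "clusters.tsv"
            return asg
        assignment = _run("cluster", _cluster)
    else:
        assignment = None

    # -- project -----------------------------------------------------------
    if cfg["project"]["enabled"]:
        def _project():
            coords = analysis.project_2d(vectors,
                                         perplexity=cfg["project"]["perplexity"],
                                         seed=seeds["project"])
            with open(out / "tsne.tsv", "w") as fh:
                for cid, (x, y) in coords.items():
                    fh.write(f"{cid}\t{x:.6g}\t{y:.6g}\n")
            artifacts["tsne"] = out / "tsne.tsv"
        _run("project", _project)

    # -- profiles ----------------------------------------------------------
    if cfg["profile"]["enabled"]:
        def _profile():
            with open(out / "length_width.tsv", "w") as fh:
                fh.write("cavity_id\tarc_length\tradius\n")
                for seq in sequences:
                    prof = analysis.length_width_profile(seq)
                    for a, r in prof.samples:
                        fh.write(f"{seq.cavity_id}\t{a:.6g}\t{r:.6g}\n")
            artifacts["length_width"] = out / "length_width.tsv"
            profs = analysis.amino_acid_profile(sequences, atoms, assignment=assignment)
            with open(out / "amino_acids.tsv", "w") as fh:
                fh.write("unit\tres_name\tcount\n")
                for prof in profs:
                    for code in sorted(prof.counts):
                        fh.write(f"{prof.unit}\t{code}\t{prof.counts[code]:.6g}\n")
            artifacts["amino_acids"] = out / "amino_acids.tsv"
        _run("profile", _profile)

    # -- manifest ----------------------------------------------------------
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    manifest = {
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "artifacts": {name: {"path": p.name, "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
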