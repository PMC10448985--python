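"""End-to-end wiring: train a model archive from FASTA+GFF3, predict on new
sequences, and run multi-stage configurations.

The model archive bundles everything prediction needs — the trained fold
models, the k-mer frequency tables estimated from the training data, and the
sensor configuration — in a single JSON file, so a prediction run cannot
accidentally mix tables and weights from different training runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import classifier, consensus, evaluation, kmer_tables, sensors, sequence_io
from .sequence_io import CdsAnnotation, PredictionTrack, SequenceRecord

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class ModelArchive:
    ensemble: classifier.ModelEnsemble
    tables: dict[int, kmer_tables.KmerFrequencyTable]
    sensor_config: sensors.SensorConfig

    def save(self, path) -> None:
        doc = {
            "format_version": 1,
            "ensemble": self.ensemble.to_dict(),
            "sensor": self.sensor_config.__dict__.copy(),
            "tables": {
                str(k): {
                    "pseudocount": t.pseudocount,
                    "p1": t.p1.tolist(),
                    "p0": t.p0.tolist(),
                }
                for k, t in self.tables.items()
            },
        }
        doc["sensor"]["kmer_ks"] = list(self.sensor_config.kmer_ks)
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "ModelArchive":
        with open(path) as fh:
            doc = json.load(fh)
        sensor_kwargs = dict(doc["sensor"])
        sensor_kwargs["kmer_ks"] = tuple(sensor_kwargs["kmer_ks"])
        return cls(
            ensemble=classifier.ModelEnsemble.from_dict(doc["ensemble"]),
            tables={
                int(k): kmer_tables.KmerFrequencyTable(
                    k=int(k), p1=np.asarray(v["p1"]), p0=np.asarray(v["p0"]),
                    pseudocount=v["pseudocount"])
                for k, v in doc["tables"].items()
            },
            sensor_config=sensors.SensorConfig(**sensor_kwargs),
        )


def sample_balanced_multi(
    tracks: list[PredictionTrack], n1: int, n0: int, seed: int
) -> list[tuple[int, np.ndarray]]:
    """Balanced sampling pooled across several tracks.

    Returns [(track_index, positions)] with n1 coding + n0 noncoding positions
    total, drawn without replacement from the pooled valid positions.
    """
    pool_track: list[np.ndarray] = []
    pool_pos: list[np.ndarray] = []
    pool_lab: list[np.ndarray] = []
    for i, tr in enumerate(tracks):
        pos = np.arange(tr.valid_start, tr.valid_end)
        pool_track.append(np.full(len(pos), i))
        pool_pos.append(pos)
        pool_lab.append(tr.labels[pos])
    track_idx = np.concatenate(pool_track)
    positions = np.concatenate(pool_pos)
    labs = np.concatenate(pool_lab)
    rng = np.random.default_rng(seed)
    chosen = []
    for want, cls in ((n1, 1), (n0, 0)):
        members = np.flatnonzero(labs == cls)
        if len(members) < want:
            raise ValueError(
                f"requested {want} class-{cls} positions, only {len(members)} "
                f"available"
            )
        chosen.append(rng.choice(members, size=want, replace=False))
    take = np.concatenate(chosen)
    return [
        (i, np.sort(positions[take[track_idx[take] == i]]))
        for i in range(len(tracks))
        if np.any(track_idx[take] == i)
    ]


def train_model(
    records: list[SequenceRecord],
    annotations: list[CdsAnnotation],
    n_samples: int,
    seed: int,
    spec: classifier.ModelSpec | None = None,
    sensor_config: sensors.SensorConfig | None = None,
    pseudocount: float = 1.0,
) -> ModelArchive:
    """Estimate k-mer tables, featurize, balanced-sample and train the
    5-fold ensemble.  n_samples is split evenly between the classes."""
    spec = spec or classifier.ModelSpec()
    sensor_config = sensor_config or sensors.SensorConfig()
    tables = {
        k: kmer_tables.estimate_tables(records, annotations, k, seed=seed,
                                       pseudocount=pseudocount)
        for k in sensor_config.kmer_ks
    }
    tracks = [
        sequence_io.label_nucleotides(rec, ann, sensor_config.window)
        for rec, ann in zip(records, annotations)
    ]
    n1 = n_samples // 2
    n0 = n_samples - n1
    sampled = sample_balanced_multi(tracks, n1, n0, seed)
    feats = []
    labels = []
    for track_i, positions in sampled:
        fm = sensors.featurize_track(records[track_i], sensor_config, tables)
        rows = positions - fm.positions[0]
        feats.append(fm.values[rows])
        labels.append(tracks[track_i].labels[positions])
    x = np.concatenate(feats)
    y = np.concatenate(labels)
    ensemble = classifier.train_ensemble(x, y, spec, seed)
    return ModelArchive(ensemble=ensemble, tables=tables,
                        sensor_config=sensor_config)


@dataclass
class PredictionResult:
    initial: PredictionTrack
    adjusted: PredictionTrack
    accepted: list[consensus.PotentialCds]
    threshold: float
    trajectory: list[tuple[float, float]] | None = None


def predict_record(
    record: SequenceRecord,
    archive: ModelArchive,
    config: consensus.ConsensusConfig,
    mode: str = "majority",
    use_sweep: bool = False,
) -> PredictionResult:
    """Initial NN predictions followed by consensus adjustment.

    With use_sweep the threshold is chosen by the fraction-targeted sweep
    (config.target_coding_fraction must be set); otherwise config.threshold
    is applied directly.
    """
    fm = sensors.featurize_track(record, archive.sensor_config, archive.tables)
    initial = classifier.predict_initial(archive.ensemble, fm, mode=mode)
    if use_sweep:
        sweep = consensus.fraction_targeted_sweep(record.seq, initial, config)
        return PredictionResult(initial, sweep.adjusted, sweep.accepted,
                                sweep.threshold, sweep.trajectory)
    adjusted, accepted = consensus.adjust_predictions(record.seq, initial,
                                                      config)
    return PredictionResult(initial, adjusted, accepted, config.threshold)


def merge_reverse_predictions(
    forward: PredictionTrack, reverse: PredictionTrack
) -> PredictionTrack:
    """Union of forward-strand labels with reverse-complement-scan labels
    mapped back to forward coordinates."""
    labels = forward.labels | reverse.labels[::-1]
    return forward.copy_with(labels)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: dict) -> dict:
    """Execute the stages named in config["stages"] in order.

    Returns a manifest of produced artifacts.  A stage failure raises
    PipelineError naming the stage.
    """
    from pathlib import Path

    from . import simulate as simulate_mod

    workdir = Path(config.get("workdir", "."))
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"config_hash": _config_hash(config), "artifacts": {}}
    state: dict = {}

    for stage in config.get("stages", []):
        params = dict(config.get(stage, {}))
        try:
            if stage == "simulate":
                params.setdefault("seed", seed)
                prefix = str(workdir / params.pop("out_prefix", "genome"))
                sim_cfg = simulate_mod.GenomeSimConfig(**params)
                fasta, gff, tsv = simulate_mod.write_fixture(sim_cfg, prefix)
                state["fasta"], state["gff"] = fasta, gff
                manifest["artifacts"][stage] = [fasta, gff, tsv]
            elif stage == "train":
                fasta = params.get("fasta", state.get("fasta"))
                gff = params.get("gff", state.get("gff"))
                if not fasta or not gff:
                    raise ValueError("train needs fasta and gff inputs")
                records = sequence_io.read_fasta(fasta)
                annotations = [
                    sequence_io.read_gff_cds(gff, r.id, len(r)) for r in records
                ]
                archive = train_model(
                    records, annotations,
                    n_samples=int(params.get("n_samples", 100_000)),
                    seed=int(params.get("seed", seed)),
                )
                model_path = str(workdir / params.get("model_out", "model.json"))
                archive.save(model_path)
                state["model"] = model_path
                manifest["artifacts"][stage] = [model_path]
            elif stage == "predict":
                fasta = params.get("fasta", state.get("fasta"))
                model_path = params.get("model", state.get("model"))
                if not fasta or not model_path:
                    raise ValueError("predict needs fasta and model inputs")
                archive = ModelArchive.load(model_path)
                cc = consensus.ConsensusConfig(
                    lmin=int(params.get("lmin", 40)),
                    lmax=int(params.get("lmax", 400)),
                    threshold=float(params.get("threshold", 1.0)),
                    target_coding_fraction=params.get("target_fraction"),
                    fraction_margin=float(params.get("margin", 0.1)),
                )
                use_sweep = params.get("target_fraction") is not None
                outs = []
                for rec in sequence_io.read_fasta(fasta):
                    res = predict_record(rec, archive, cc, use_sweep=use_sweep)
                    bed = str(workdir / f"{rec.id}.predicted.bed")
                    track = str(workdir / f"{rec.id}.predicted.tsv")
                    sequence_io.write_bed(res.accepted, bed, seq_id=rec.id)
                    sequence_io.write_track_tsv(res.adjusted, track)
                    outs.extend([bed, track])
                    state["pred_track"] = track
                manifest["artifacts"][stage] = outs
            elif stage == "evaluate":
                track_path = params.get("pred_track", state.get("pred_track"))
                gff = params.get("truth_gff", state.get("gff"))
                if not track_path or not gff:
                    raise ValueError("evaluate needs pred_track and truth_gff")
                pred = sequence_io.read_track_tsv(track_path)
                truth_ann = sequence_io.read_gff_cds(
                    gff, pred.seq_id, len(pred.labels))
                truth_labels = np.zeros(len(pred.labels), dtype=np.uint8)
                for s, e in truth_ann.intervals:
                    truth_labels[s:e] = 1
                truth = PredictionTrack(pred.seq_id, truth_labels,
                                        pred.valid_start, pred.valid_end)
                report = evaluation.metrics(evaluation.confusion(pred, truth))
                report_path = str(workdir / params.get("report_out",
                                                       "report.json"))
                with open(report_path, "w") as fh:
                    json.dump(report.to_dict(), fh, indent=2)
                manifest["artifacts"][stage] = [report_path]
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    manifest_path = workdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
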