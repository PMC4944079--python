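"""End-to-end pipeline: normalize -> signature -> melodies -> comparison.

Two-phase usage mirrors the intended study design: a *define-signature* run
on reference samples produces a signature file; an *apply-signature* run
combines new samples with the references, re-normalizes jointly and
restricts to the stored signature before sonification and clustering.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from . import __version__
from .comparison import (
    FeatureSpace,
    compare_groups,
    melody_feature_matrix,
    pairwise_manhattan,
    complete_linkage,
    relative_correlation,
    to_newick,
    write_distance_matrix,
)
from .matrix import ExpressionMatrix, normalize_quantile, read_matrix, to_log2, write_matrix
from .midi import write_midi
from .signature import apply_signature, read_signature, select_high_variance, write_signature
from .sonification import Melody, ScaleConfig, calibrate, sonify_sample, write_note_table, write_score_text

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_annotations"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``fraction`` / ``n`` selects the signature size when a
    new signature is defined; ``signature_path`` instead applies a stored
    signature. ``annotations`` (sample -> group, role) enables the
    relative-correlation report; roles are ``control``, ``perturbed`` and
    ``reference``.
    """

    matrix_path: Path
    out_dir: Path
    scale_hint: Literal["linear", "log2"] = "log2"
    fraction: float | None = 0.05
    n: int | None = None
    signature_path: Path | None = None
    annotations_path: Path | None = None
    reference_group: str | None = None
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    feature_space: FeatureSpace = "frequency"
    write_midi_files: bool = True
    score_bars: tuple[int, int] | None = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix_path", Path(self.matrix_path))
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.signature_path is not None:
            object.__setattr__(self, "signature_path", Path(self.signature_path))
            if self.n is not None or (self.fraction is not None and self.fraction != 0.05):
                raise ValueError("signature_path excludes fraction/n selection")
        elif (self.fraction is None) == (self.n is None):
            raise ValueError("set exactly one of fraction or n (or a signature_path)")
        if self.annotations_path is not None:
            object.__setattr__(self, "annotations_path", Path(self.annotations_path))


def read_annotations(path: Path) -> dict[str, tuple[str, str]]:
    """Read a sample annotation TSV: sample_id <TAB> group <TAB> role."""
    out: dict[str, tuple[str, str]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "group", "role"]:
            raise PipelineError(f"annotations {path}: expected header sample_id/group/role")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PipelineError(f"annotations {path}:{lineno}: expected 3 fields")
            sid, group, role = parts
            if role not in ("control", "perturbed", "reference", ""):
                raise PipelineError(f"annotations {path}:{lineno}: unknown role {role!r}")
            out[sid] = (group, role)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(quiet: bool, stage: str, t0: float) -> None:
    if not quiet:
        print(f"[gemusica] {stage} ({time.perf_counter() - t0:.2f}s)", file=sys.stderr)


def run_pipeline(config: PipelineConfig, *, quiet: bool = True) -> dict[str, Path]:
    """Run the full pipeline and write the artifact bundle.

    Returns a name -> path map of the written artifacts (signature TSV,
    normalized matrix, per-sample note tables / MIDI / score text, distance
    TSV, Newick tree, optional correlation report, run manifest). Outputs
    are deterministic for fixed inputs and configuration.
    """
    cfg = config
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t0 = time.perf_counter()

    try:
        m = read_matrix(cfg.matrix_path, cfg.scale_hint)
        m = to_log2(m)
    except Exception as e:
        raise PipelineError(f"read: {e}") from e
    _log(quiet, f"read {m.n_probes}x{m.n_samples} matrix", t0)

    try:
        m = normalize_quantile(m)
    except Exception as e:
        raise PipelineError(f"normalize: {e}") from e
    artifacts["normalized_matrix"] = out / "normalized_matrix.tsv"
    write_matrix(m, artifacts["normalized_matrix"])
    _log(quiet, "quantile normalization", t0)

    try:
        if cfg.signature_path is not None:
            sig = read_signature(cfg.signature_path)
        elif cfg.fraction is not None:
            sig = select_high_variance(m, fraction=cfg.fraction)
        else:
            sig = select_high_variance(m, n=cfg.n)
        restricted = apply_signature(m, sig)
    except Exception as e:
        raise PipelineError(f"signature: {e}") from e
    artifacts["signature"] = out / "signature.tsv"
    write_signature(sig, artifacts["signature"])
    _log(quiet, f"signature of {sig.n} probe sets", t0)

    try:
        cal = calibrate(restricted)
        melodies = [sonify_sample(restricted, sid, cfg.scale, cal) for sid in restricted.sample_ids]
    except Exception as e:
        raise PipelineError(f"sonify: {e}") from e
    mel_dir = out / "melodies"
    mel_dir.mkdir(exist_ok=True)
    for mel in melodies:
        base = mel_dir / mel.sample_id
        write_note_table(mel, base.with_suffix(".csv"))
        artifacts[f"notes:{mel.sample_id}"] = base.with_suffix(".csv")
        if cfg.write_midi_files:
            write_midi(mel, base.with_suffix(".mid"))
            artifacts[f"midi:{mel.sample_id}"] = base.with_suffix(".mid")
        if cfg.score_bars is not None:
            write_score_text(mel, base.with_suffix(".ly"), *cfg.score_bars)
            artifacts[f"score:{mel.sample_id}"] = base.with_suffix(".ly")
    _log(quiet, f"{len(melodies)} melodies", t0)

    try:
        features = melody_feature_matrix(melodies, cfg.feature_space)
        dm = pairwise_manhattan(features)
        tree = complete_linkage(dm)
    except Exception as e:
        raise PipelineError(f"compare: {e}") from e
    artifacts["distances"] = out / "distances.tsv"
    write_distance_matrix(dm, artifacts["distances"])
    artifacts["tree"] = out / "tree.nwk"
    artifacts["tree"].write_text(to_newick(tree) + "\n", encoding="utf-8")
    _log(quiet, "clustering", t0)

    if cfg.annotations_path is not None:
        try:
            ann = read_annotations(cfg.annotations_path)
            ref_group = cfg.reference_group
            controls = [s for s in features.sample_ids if ann.get(s, ("", ""))[1] == "control"]
            perturbed = [s for s in features.sample_ids if ann.get(s, ("", ""))[1] == "perturbed"]
            refs = [
                s
                for s in features.sample_ids
                if ann.get(s, ("", ""))[1] == "reference"
                and (ref_group is None or ann[s][0] == ref_group)
            ]
            report = relative_correlation(
                features, controls, perturbed, refs, reference_group=ref_group or "reference"
            )
            test = compare_groups(report)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"correlation report: {e}") from e
        artifacts["report_csv"] = out / "correlation_report.csv"
        with artifacts["report_csv"].open("w", encoding="utf-8") as fh:
            fh.write("sample_id,group,rho,rho_rel\n")
            for sid in (*report.control_ids, *report.perturbed_ids):
                grp = "control" if sid in report.control_ids else "perturbed"
                fh.write(f"{sid},{grp},{report.rho[sid]!r},{report.rho_rel[sid]!r}\n")
        artifacts["report_json"] = out / "correlation_report.json"
        summary = json.loads(report.to_json())
        summary["welch"] = {"statistic": test.statistic, "df": test.df, "pvalue": test.pvalue}
        artifacts["report_json"].write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
        _log(quiet, "correlation report", t0)
    elif cfg.reference_group is not None:
        raise PipelineError("correlation report requested but no annotations file given")

    manifest = {
        "package": "gemusica",
        "version": __version__,
        "seed": cfg.seed,
        "matrix": {"path": str(cfg.matrix_path), "sha256": _sha256(cfg.matrix_path)},
        "parameters": {
            "scale_hint": cfg.scale_hint,
            "fraction": cfg.fraction,
            "n": cfg.n,
            "signature_path": str(cfg.signature_path) if cfg.signature_path else None,
            "feature_space": cfg.feature_space,
            "minfreq": cfg.scale.minfreq,
            "tonesteps": cfg.scale.tonesteps,
            "numkeys": cfg.scale.numkeys,
            "mindur": cfg.scale.mindur,
            "maxNdots": cfg.scale.maxNdots,
            "vol": cfg.scale.vol,
            "meter": f"{cfg.scale.meter[0]}/{cfg.scale.meter[1]}",
        },
        "n_probes": m.n_probes,
        "n_samples": m.n_samples,
        "signature_size": sig.n,
    }
    artifacts["manifest"] = out / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return artifacts


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file mirroring the CLI flags."""
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    scale_keys = {"minfreq", "tonesteps", "numkeys", "mindur", "maxNdots", "vol", "meter"}
    scale_kwargs = {k: raw.pop(k) for k in list(raw) if k in scale_keys}
    if "meter" in scale_kwargs and isinstance(scale_kwargs["meter"], str):
        num, den = scale_kwargs["meter"].split("/")
        scale_kwargs["meter"] = (int(num), int(den))
    if "score_bars" in raw and raw["score_bars"] is not None:
        raw["score_bars"] = tuple(raw["score_bars"])
    return PipelineConfig(scale=ScaleConfig(**scale_kwargs), **raw)
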