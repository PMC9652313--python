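"""Run manifest: a deterministic inventory of every stage artifact.

The manifest records, for each artifact, its stage, relative path and
content hash, plus a hash of the run configuration, so a rerun with the
same config and seed can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .io_core import ValidationError

STAGE_OUTPUTS = {
    "simulate": ["inputs"],
    "integrate": ["integrate"],
    "conserve": ["conserve"],
    "metaneighbor": ["metaneighbor"],
    "modules": ["modules"],
    "enrich": ["enrich"],
    "regulons": ["regulons"],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_report(run_dir: str | Path) -> dict:
    """Collect all stage artifacts into ``report/manifest.json``.

    Raises if a stage directory is missing, naming the stage to run.
    """
    run_dir = Path(run_dir)
    config_path = run_dir / "config_used.yaml"
    if not config_path.exists():
        raise ValidationError("missing config_used.yaml; run the simulate stage")
    stages = []
    artifacts = []
    for stage, dirs in STAGE_OUTPUTS.items():
        for d in dirs:
            stage_dir = run_dir / d
            if not stage_dir.exists():
                raise ValidationError(
                    f"missing output of stage {stage!r}; run `crossneuro "
                    f"{stage}` first"
                )
            for f in sorted(stage_dir.rglob("*")):
                if f.is_file():
                    artifacts.append(
                        {
                            "stage": stage,
                            "path": str(f.relative_to(run_dir)),
                            "sha256": _sha256(f),
                        }
                    )
        stages.append(stage)
    stages.append("report")
    manifest = {
        "stages": stages,
        "config_sha256": _sha256(config_path),
        "artifacts": artifacts,
    }
    out = run_dir / "report"
    out.mkdir(exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
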