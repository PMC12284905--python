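"""Structured emission of campaign results: CSV records plus a JSON manifest.

The manifest echoes every resolved parameter, the package version, the base
seed and the per-replicate seeds, so a run can be reproduced bit-for-bit from
the manifest alone.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .experiments import Campaign

__all__ = ["RunManifest", "build_manifest", "write_records", "write_manifest"]


@dataclass
class RunManifest:
    command: str
    version: str
    params: dict
    replicates: int
    years: int
    carryover: str
    base_seed: int
    replicate_seeds: list[int]
    created: str
    outputs: list[str] = field(default_factory=list)


def build_manifest(command: str, campaign: Campaign) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        version=__version__,
        params=dataclasses.asdict(campaign.params),
        replicates=campaign.replicates,
        years=campaign.years,
        carryover=campaign.carryover,
        base_seed=campaign.base_seed,
        replicate_seeds=[campaign.base_seed + i for i in range(campaign.replicates)],
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )


def write_records(
    records: pd.DataFrame, path, manifest: RunManifest | None = None
) -> Path:
    """Write records as CSV (fixed header order, full float precision).

    When a manifest is given it is written alongside as ``<stem>.manifest.json``
    with the CSV registered in its output inventory.
    """
    if len(records) == 0:
        raise ValueError("refusing to write an empty record set")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)
    if manifest is not None:
        manifest.outputs.append(path.name)
        write_manifest(manifest, path.with_suffix(".manifest.json"))
    return path


def write_manifest(manifest: RunManifest, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return path
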