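"""Scenario configuration: YAML/JSON files mirroring the model parameters.

A config file maps parameter names one-to-one onto :class:`ModelParams`
fields, plus the campaign keys ``replicates``, ``years``, ``carryover`` and
``base_seed``.  CLI overrides take precedence over file values.  CI strength
may be given either as explicit ``sigma_fm``/``sigma_md`` components (their
sum defines ``sigma_total``) or as a ``sigma_total`` next to components that
then act as proportions and are rescaled to sum to it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .experiments import Campaign
from .params import ModelParams

__all__ = ["load_config", "load_campaign"]

_CAMPAIGN_KEYS = {"replicates", "years", "carryover", "base_seed"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}


def _read_file(path) -> dict:
    text = Path(path).read_text()
    if not text.strip():
        return {}
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping of parameter names")
    return data


def _resolve_ci(values: dict) -> dict:
    """Reconcile sigma_fm/sigma_md/sigma_total, rescaling proportions if needed."""
    fm = values.get("sigma_fm")
    md = values.get("sigma_md")
    total = values.get("sigma_total")
    if fm is None and md is None:
        if total not in (None, 0, 0.0):
            raise ValueError(
                "sigma_total given without sigma_fm/sigma_md: the FM:MD split is undefined"
            )
        return values
    fm = 0.0 if fm is None else float(fm)
    md = 0.0 if md is None else float(md)
    if total is None:
        values.update(sigma_fm=fm, sigma_md=md, sigma_total=fm + md)
        return values
    total = float(total)
    comp = fm + md
    if abs(comp - total) <= 1e-9:
        values.update(sigma_fm=fm, sigma_md=md, sigma_total=total)
    elif comp > 0:
        values.update(sigma_fm=fm / comp * total, sigma_md=md / comp * total, sigma_total=total)
    elif total > 0:
        raise ValueError("cannot rescale sigma_fm = sigma_md = 0 to a non-zero sigma_total")
    return values


def load_config(path=None, cli_overrides: dict | None = None) -> ModelParams:
    """Build validated :class:`ModelParams` from a file plus overrides.

    An absent or empty file yields the default parameter set.  Unknown keys
    and out-of-range values raise ``ValueError`` with a targeted message.
    """
    values = _read_file(path) if path is not None else {}
    values = {k: v for k, v in values.items() if k not in _CAMPAIGN_KEYS}
    if cli_overrides:
        values.update({k: v for k, v in cli_overrides.items() if v is not None})
    unknown = set(values) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown parameter(s) in config: {sorted(unknown)}")
    values = _resolve_ci(values)
    return ModelParams(**values)


def load_campaign(path=None, cli_overrides: dict | None = None) -> Campaign:
    """Build a :class:`Campaign` (parameters plus replication settings)."""
    raw = _read_file(path) if path is not None else {}
    overrides = dict(cli_overrides or {})
    campaign_kwargs = {}
    for key in _CAMPAIGN_KEYS:
        if key in overrides and overrides[key] is not None:
            campaign_kwargs[key] = overrides.pop(key)
        elif key in raw:
            campaign_kwargs[key] = raw[key]
    params = load_config(path, overrides) if path is not None else load_config(None, overrides)
    return Campaign(params=params, **campaign_kwargs)
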