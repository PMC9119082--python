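"""YAML (de)serialisation of the configuration dataclasses.

One YAML file can describe a whole experiment::

    net:
      variant: 4
      n_classes: 3
      in_channels: 1
      encoder: {stage_depths: [3,4,6,3], stage_widths: [64,128,256,512],
                stage_strides: [2,2,2,1], stem_width: 64}
      transformer: {patch_size: 8, embed_width: 512, n_layers: 2, n_heads: 8}
    train:
      epochs: 80
      batch_size: 3
      learning_rate: 0.001
    phantom:
      image_size: 128
      archetype: organ_with_inclusions
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .assembly import NetConfig
from .global_branch import TransformerConfig
from .local_branch import AggregationPlan, EncoderConfig
from .phantom import PhantomSpec, _spec_from_dict
from .training import TrainConfig


def _tuplify(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d


def net_config_from_dict(d: dict) -> NetConfig:
    d = dict(d)
    if d.get("encoder"):
        d["encoder"] = EncoderConfig(**_tuplify(
            d["encoder"], ("stage_depths", "stage_widths", "stage_strides")))
    if d.get("plan") is not None:
        nodes = tuple(tuple(n) for n in d["plan"])
        d["plan"] = AggregationPlan(nodes)
    if d.get("transformer"):
        d["transformer"] = TransformerConfig(**d["transformer"])
    if "decoder_widths" in d:
        d["decoder_widths"] = tuple(d["decoder_widths"])
    return NetConfig(**d)


def net_config_to_dict(cfg: NetConfig) -> dict:
    return {
        "variant": cfg.variant,
        "n_classes": cfg.n_classes,
        "in_channels": cfg.in_channels,
        "encoder": asdict(cfg.encoder) if cfg.encoder else None,
        "plan": [list(n) for n in cfg.plan.nodes] if cfg.plan else None,
        "transformer": asdict(cfg.transformer) if cfg.transformer else None,
        "decoder_widths": list(cfg.decoder_widths),
        "dropout": cfg.dropout,
    }


def load_experiment(path: str | Path) -> dict:
    """Read an experiment YAML into config objects (missing blocks -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {
        "net": net_config_from_dict(raw.get("net", {})),
        "train": TrainConfig(**raw.get("train", {})),
        "phantom": PhantomSpec(**_spec_from_dict(raw["phantom"]))
        if "phantom" in raw else PhantomSpec(),
        "raw": raw,
    }


def save_experiment(path: str | Path, net: NetConfig | None = None,
                    train: TrainConfig | None = None,
                    phantom: PhantomSpec | None = None):
    """Write a config echo next to run outputs."""
    blob: dict = {}
    if net is not None:
        blob["net"] = net_config_to_dict(net)
    if train is not None:
        blob["train"] = asdict(train)
    if phantom is not None:
        blob["phantom"] = asdict(phantom)
    Path(path).write_text(yaml.safe_dump(_listify(blob), sort_keys=False))


def _listify(obj):
    """Recursively turn tuples into lists so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj
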