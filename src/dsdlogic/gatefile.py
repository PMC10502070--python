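"""Read and write gate-specification files.

The on-disk format is structured text with three sections::

    name: OR
    domains:
      - {name: E, role: toehold, length_nt: 6}
      - {name: F, role: recognition, length_nt: 15}
      ...
    strands:
      - {name: EFHG, domains: [E, F, H, G], label: quencher_BHQ1}
      - {name: fh, domains: [f, h], label: fluorophore_FAM}
      - {name: efh, domains: [e, f, h]}
      ...
    gate:
      template: EFHG
      incumbent: fh
      incumbent_footprint: [2, 3]
      inputs: [efh, fhg, efhg]
    kinetics:        # optional overrides for the kinetic engine
      copies: 100
      t_end: 10000.0

Lowercase complements of declared domains are implied.  Files ending in
``.json`` use the identical structure rendered as JSON; everything else is
parsed as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml

from .core import GateSystem, ValidationError, build_gate_system
from .kinetics import RateParameters

__all__ = ["read_gate_file", "write_gate_file", "gate_to_spec", "kinetics_from_spec"]


def gate_to_spec(gate: GateSystem) -> dict:
    """Serializable specification record for a gate system."""
    seen = set()
    domain_recs = []
    for d in gate.template.domains:
        canonical = d if d.is_canonical else d.complement()
        if canonical.name not in seen:
            seen.add(canonical.name)
            domain_recs.append({
                "name": canonical.name,
                "role": canonical.role,
                "length_nt": canonical.length_nt,
            })
    strand_recs = []
    strand_seen = set()
    for s in gate.all_strands():
        if s.name in strand_seen and s.label is None:
            continue  # the incumbent twin is declared once, unlabelled inputs skip
        strand_seen.add(s.name)
        rec = {"name": s.name, "domains": list(s.domain_names)}
        if s.label:
            rec["label"] = s.label
        strand_recs.append(rec)
    return {
        "name": gate.name,
        "domains": domain_recs,
        "strands": strand_recs,
        "gate": {
            "name": gate.name,
            "template": gate.template.name,
            "incumbent": gate.incumbent.name,
            "incumbent_footprint": list(gate.incumbent_footprint),
            "inputs": [s.name for s in gate.inputs],
        },
    }


def write_gate_file(gate: GateSystem, path) -> None:
    path = Path(path)
    spec = gate_to_spec(gate)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(spec, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(spec, sort_keys=True))


def _load_spec(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gate file {path} does not exist")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            spec = json.loads(text)
        else:
            spec = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValidationError(f"gate file {path} cannot be parsed: {exc}") from exc
    if not isinstance(spec, dict):
        raise ValidationError(f"gate file {path} does not hold a mapping")
    return spec


def read_gate_file(path) -> GateSystem:
    return build_gate_system(_load_spec(path))


def kinetics_from_spec(path, **overrides) -> RateParameters:
    """Rate parameters from the file's optional ``kinetics`` section.

    Keyword overrides (e.g. CLI flags) win over the file's values.
    """
    section = dict(_load_spec(path).get("kinetics", {}))
    section.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(RateParameters.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ValidationError(f"unknown kinetics settings: {sorted(unknown)}")
    return RateParameters(**section)
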