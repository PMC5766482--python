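"""YAML round-tripping for the package-wide parameter sets."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from . import polymer_models as pm
from .domain_kinetics import RateSet
from .states import Redox


def _redox_dict_to_yaml(d: dict) -> dict:
    return {rx.value: v for rx, v in d.items()}


def _redox_dict_from_yaml(d: dict) -> dict:
    return {Redox(k): v for k, v in d.items()}


def dump_config(path, params: pm.PolymerParams | None = None,
                geom: pm.DomainGeometry | None = None,
                topo: pm.DisulfideTopology | None = None,
                rates: RateSet | None = None) -> None:
    params = params or pm.PolymerParams()
    geom = geom or pm.DomainGeometry()
    topo = topo or pm.DisulfideTopology()
    rates = rates or RateSet()
    doc = {
        "polymer": asdict(params),
        "geometry": asdict(geom),
        "topology": asdict(topo),
        "rates": {
            "k0_u": _redox_dict_to_yaml(rates.k0_u),
            "dx_u": _redox_dict_to_yaml(rates.dx_u),
            "k_fold": _redox_dict_to_yaml(rates.k_fold),
            "k_iso1": rates.k_iso1, "k_iso2": rates.k_iso2,
            "dx_iso": rates.dx_iso, "k_red2": rates.k_red2,
            "tcep_mM": rates.tcep_mM, "k_reiso": rates.k_reiso,
            "refold_force_max": rates.refold_force_max, "kT": rates.kT,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path):
    """Load (PolymerParams, DomainGeometry, DisulfideTopology, RateSet)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = pm.PolymerParams(**doc.get("polymer", {}))
    geom = pm.DomainGeometry(**doc.get("geometry", {}))
    topo = pm.DisulfideTopology(**doc.get("topology", {}))
    r = doc.get("rates", {})
    kwargs = dict(r)
    for key in ("k0_u", "dx_u", "k_fold"):
        if key in kwargs:
            kwargs[key] = _redox_dict_from_yaml(kwargs[key])
    rates = RateSet(**kwargs)
    return params, geom, topo, rates
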