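"""Run configuration: JSON schema, chain/protocol loading, serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import OpenChain, make_chain
from .protocols import (ArrivalProtocol, bernoulli_product_protocol,
                        constant_protocol, joint_pmf_protocol,
                        paired_bernoulli_protocol, poisson_product_protocol)

__all__ = ["RunConfig", "load_config", "chain_from_spec", "protocol_from_spec",
           "read_jump_matrix"]


@dataclass
class RunConfig:
    """Validated settings for a simulate/analyze/correlate run."""

    chain: OpenChain
    protocol: ArrivalProtocol
    N0: np.ndarray
    T: int = 10_000
    replicates: int = 1
    burn_in: int | None = None
    seed: int = 0
    max_lag: int = 10
    raw: dict = field(default_factory=dict)


def read_jump_matrix(source, base_dir: Path | None = None) -> np.ndarray:
    """Jump matrix from nested JSON arrays or a headerless CSV path."""
    if isinstance(source, str):
        path = Path(source)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            raise ValueError(f"config field 'Q': file {path} does not exist")
        return pd.read_csv(path, header=None).to_numpy(dtype=float)
    try:
        return np.asarray(source, dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"config field 'Q': not a rectangular numeric matrix ({err})")


def chain_from_spec(spec, base_dir: Path | None = None) -> OpenChain:
    return make_chain(read_jump_matrix(spec, base_dir))


def protocol_from_spec(spec: dict, base_dir: Path | None = None) -> ArrivalProtocol:
    """Build an arrival protocol from its config dict.

    Supported: ``{"type": "constant", "J0": [...]}, {"type": "bernoulli",
    "p": [...]}, {"type": "poisson", "lam": [...]},
    {"type": "paired_bernoulli", "p": x}, {"type": "table", "table": [...]}``
    or ``{"type": "table", "csv": "path"}`` with columns ``j_1..j_S, prob``.
    """
    if not isinstance(spec, dict) or "type" not in spec:
        raise ValueError("config field 'protocol': must be an object with a 'type' key")
    kind = spec["type"]
    try:
        if kind == "constant":
            return constant_protocol(spec["J0"])
        if kind == "bernoulli":
            return bernoulli_product_protocol(spec["p"])
        if kind == "poisson":
            return poisson_product_protocol(spec["lam"])
        if kind == "paired_bernoulli":
            return paired_bernoulli_protocol(float(spec["p"]))
        if kind == "table":
            if "csv" in spec:
                path = Path(spec["csv"])
                if base_dir is not None and not path.is_absolute():
                    path = base_dir / path
                df = pd.read_csv(path)
                jcols = [c for c in df.columns if c.startswith("j_")]
                if not jcols or "prob" not in df.columns:
                    raise ValueError("pmf CSV needs columns j_1..j_S and prob")
                table = [(row[jcols].to_numpy(), float(row["prob"]))
                         for _, row in df.iterrows()]
            else:
                table = [(np.asarray(v), float(p)) for v, p in spec["table"]]
            return joint_pmf_protocol(table)
    except KeyError as err:
        raise ValueError(f"config field 'protocol': missing parameter {err} for type {kind!r}")
    raise ValueError(f"config field 'protocol.type': unknown type {kind!r}")


def load_config(path) -> RunConfig:
    """Load and validate a run configuration from a JSON file.

    Required keys: ``Q`` (nested arrays or CSV path) and ``protocol``.
    Optional: ``N0`` (default zeros), ``T``, ``replicates``, ``burn_in``
    (default: the simulator burn-in rule), ``seed``, ``max_lag``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    if "Q" not in raw:
        raise ValueError("config field 'Q' is required")
    if "protocol" not in raw:
        raise ValueError("config field 'protocol' is required")
    chain = chain_from_spec(raw["Q"], base_dir=path.parent)
    protocol = protocol_from_spec(raw["protocol"], base_dir=path.parent)
    if protocol.S != chain.S:
        raise ValueError(
            f"config: protocol dimension {protocol.S} does not match chain S={chain.S}")
    N0 = np.asarray(raw.get("N0", np.zeros(chain.S)), dtype=float)
    if N0.shape != (chain.S,) or np.any(N0 < 0) or np.any(N0 != np.round(N0)):
        raise ValueError("config field 'N0': must be a length-S vector of nonnegative integers")
    T = int(raw.get("T", 10_000))
    if T < 1:
        raise ValueError("config field 'T': must be >= 1")
    replicates = int(raw.get("replicates", 1))
    if replicates < 1:
        raise ValueError("config field 'replicates': must be >= 1")
    burn_in = raw.get("burn_in")
    if burn_in is not None:
        burn_in = int(burn_in)
        if burn_in < 0:
            raise ValueError("config field 'burn_in': must be >= 0")
    max_lag = int(raw.get("max_lag", 10))
    if max_lag < 0:
        raise ValueError("config field 'max_lag': must be >= 0")
    return RunConfig(chain=chain, protocol=protocol, N0=N0.astype(np.int64), T=T,
                     replicates=replicates, burn_in=burn_in,
                     seed=int(raw.get("seed", 0)), max_lag=max_lag, raw=raw)
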