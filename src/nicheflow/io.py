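"""File formats: edge lists, parameter JSON, records CSV, INI configs.

Species IDs are 1-based in every file and 0-based in memory.  Edge lists
are TSV with a ``consumer\tresource`` header; a JSON sidecar carries the
niche attributes (n, r, c) needed to reconstruct a TopologicalWeb exactly.
Numeric CSV output uses 10 significant digits so round-trips stay within
test tolerances.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .nichemodel import TopologicalWeb
from .trophic import ParametrizedWeb
from .scan import ScanConfig, DEFAULT_SIZES, DEFAULT_CONNECTANCES

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "write_adjacency_csv",
    "pweb_to_json",
    "pweb_from_json",
    "read_scan_config",
    "config_hash",
]

FLOAT_FMT = "%.10g"
# records feed the statistical stages: round-tripping them must be exact so
# `scan` followed by `analyze` reproduces the same fits bit for bit
RECORDS_FLOAT_FMT = "%.17g"


class EdgeListError(ValueError):
    pass


def write_edge_list(web: TopologicalWeb, path: str | Path, sidecar: bool = True) -> None:
    """Write a TSV edge list (1-based IDs) plus a JSON niche-attribute sidecar."""
    path = Path(path)
    rows, cols = np.nonzero(web.A)
    with open(path, "w") as fh:
        fh.write("consumer\tresource\n")
        for i, j in zip(rows, cols):
            fh.write(f"{i + 1}\t{j + 1}\n")
    if sidecar:
        meta = {
            "S": web.S,
            "C_target": web.C_target,
            "n": web.n.tolist(),
            "r": web.r.tolist(),
            "c": web.c.tolist(),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_edge_list(path: str | Path) -> TopologicalWeb:
    """Read a consumer/resource TSV edge list into a TopologicalWeb.

    Integer IDs are taken as 1-based species indices (preserving the
    writer's ordering and any isolated species implied by the sidecar);
    non-numeric IDs are indexed in order of first appearance.  Duplicate
    edges are deduplicated with a warning.  If a niche-attribute sidecar
    ``<path>.json`` exists it is used to restore n, r, c and S.
    """
    path = Path(path)
    raw_edges: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().lower().replace(" ", "") not in ("consumer\tresource", "consumer,resource"):
            raise EdgeListError(f"{path}: line 1: expected 'consumer<TAB>resource' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            parts = [p.strip() for p in parts]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise EdgeListError(f"{path}: line {lineno}: malformed row {line!r}")
            raw_edges.append((parts[0], parts[1]))

    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None

    numeric = all(a.isdigit() and b.isdigit() for a, b in raw_edges)
    if numeric:
        edges = [(int(a) - 1, int(b) - 1) for a, b in raw_edges]
        max_id = max((max(i, j) for i, j in edges), default=-1) + 1
        S = meta["S"] if meta else max_id
        if max_id > S:
            raise EdgeListError(f"{path}: species ID {max_id} exceeds sidecar count {S}")
    else:
        ids: dict[str, int] = {}
        for a, b in raw_edges:
            for token in (a, b):
                if token not in ids:
                    ids[token] = len(ids)
        edges = [(ids[a], ids[b]) for a, b in raw_edges]
        S = meta["S"] if meta else len(ids)
    A = np.zeros((S, S), dtype=np.int8)
    seen = set()
    dups = 0
    for i, j in edges:
        if (i, j) in seen:
            dups += 1
            continue
        seen.add((i, j))
        A[i, j] = 1
    if dups:
        warnings.warn(f"{path}: {dups} duplicate edge(s) ignored", stacklevel=2)
    if meta:
        n = np.asarray(meta["n"], dtype=float)
        r = np.asarray(meta["r"], dtype=float)
        c = np.asarray(meta["c"], dtype=float)
        C_target = float(meta["C_target"])
    else:
        n = r = c = np.full(S, np.nan)
        C_target = A.sum() / S**2
    return TopologicalWeb(S=S, C_target=C_target, n=n, r=r, c=c, A=A)


def write_adjacency_csv(web: TopologicalWeb, path: str | Path) -> None:
    """0/1 adjacency matrix CSV, rows = consumers, 1-based ID headers."""
    ids = [str(i + 1) for i in range(web.S)]
    pd.DataFrame(web.A, index=ids, columns=ids).to_csv(path, index_label="consumer")


def pweb_to_json(pweb: ParametrizedWeb) -> str:
    """Serialize a ParametrizedWeb (topology + all parameters) to JSON."""
    doc = {
        "S": pweb.S,
        "C_target": pweb.web.C_target,
        "adjacency": pweb.A.tolist(),
        "niche": {"n": pweb.web.n.tolist(), "r": pweb.web.r.tolist(),
                  "c": pweb.web.c.tolist()},
        "TL": pweb.TL.tolist(),
        "TL_flow": pweb.TL_flow.tolist(),
        "TL_distance": pweb.TL_distance.tolist(),
        "is_producer": pweb.is_producer.astype(int).tolist(),
        "m": pweb.m.tolist(),
        "x": pweb.x.tolist(),
        "r": pweb.r.tolist(),
        "K": pweb.K.tolist(),
        "e_col": pweb.e_col.tolist(),
        "y": pweb.y, "q": pweb.q, "c": pweb.c, "B0": pweb.B0,
    }
    return json.dumps(doc)


def pweb_from_json(text: str) -> ParametrizedWeb:
    doc = json.loads(text)
    web = TopologicalWeb(
        S=doc["S"],
        C_target=doc["C_target"],
        n=np.asarray(doc["niche"]["n"], dtype=float),
        r=np.asarray(doc["niche"]["r"], dtype=float),
        c=np.asarray(doc["niche"]["c"], dtype=float),
        A=np.asarray(doc["adjacency"], dtype=np.int8),
    )
    return ParametrizedWeb(
        web=web,
        TL=np.asarray(doc["TL"], dtype=float),
        TL_flow=np.asarray(doc["TL_flow"], dtype=float),
        TL_distance=np.asarray(doc["TL_distance"], dtype=float),
        is_producer=np.asarray(doc["is_producer"], dtype=bool),
        m=np.asarray(doc["m"], dtype=float),
        x=np.asarray(doc["x"], dtype=float),
        r=np.asarray(doc["r"], dtype=float),
        K=np.asarray(doc["K"], dtype=float),
        e_col=np.asarray(doc["e_col"], dtype=float),
        y=doc["y"], q=doc["q"], c=doc["c"], B0=doc["B0"],
    )


def read_scan_config(path: str | Path) -> ScanConfig:
    """Read an INI-style scan config; missing keys take the study defaults.

    Recognized keys (section [scan]): sizes (comma list or lo:hi:step),
    connectances, replicates, master_seed, duration_phase1, duration_phase2,
    dt, extinction_threshold, window.
    """
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    sec = parser["scan"] if parser.has_section("scan") else parser["DEFAULT"]

    def parse_list(value: str, cast):
        value = value.strip()
        if ":" in value:
            lo, hi, step = (float(v) for v in value.split(":"))
            out = np.arange(lo, hi + step * 0.5, step)
            return tuple(cast(round(v, 10)) for v in out)
        return tuple(cast(v) for v in value.split(","))

    kwargs: dict = {}
    if "sizes" in sec:
        kwargs["sizes"] = parse_list(sec["sizes"], int)
    if "connectances" in sec:
        kwargs["connectances"] = tuple(
            round(v, 6) for v in parse_list(sec["connectances"], float)
        )
    for key, cast in [("replicates", int), ("master_seed", int),
                      ("duration_phase1", int), ("duration_phase2", int),
                      ("dt", float), ("extinction_threshold", float),
                      ("window", int)]:
        if key in sec:
            kwargs[key] = cast(sec[key])
    return ScanConfig(**kwargs)


def config_hash(config: ScanConfig) -> str:
    """Short provenance hash of a scan configuration."""
    payload = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
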