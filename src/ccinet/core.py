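"""Domain containers and plain-text I/O for multilayer chaperone-client networks.

A chaperone-client interaction (CCI) network is a binary bipartite graph:
rows are chaperones, columns are client proteins. One such network per
environment (cancer type) gives a multilayer network in which every layer
shares the same node sets. On disk each layer is a TSV edge list with a
``chaperone\tclient`` header; a YAML manifest fixes the layer order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MultilayerNetwork",
    "ExpressionMatrix",
    "read_network_layers",
    "write_network_layers",
    "read_expression",
    "write_expression",
    "validate_multilayer",
    "validate_layer_frames",
    "ValidationReport",
]


@dataclass
class MultilayerNetwork:
    """Aligned binary bipartite layers over shared chaperone/client node sets.

    ``incidence`` has shape (n_chaperones, n_clients, n_layers); entry 1 in
    layer ``a`` means chaperone ``i`` interacts with client ``j`` in that
    environment.
    """

    chaperone_ids: list[str]
    client_ids: list[str]
    layer_ids: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        expected = (len(self.chaperone_ids), len(self.client_ids), len(self.layer_ids))
        if self.incidence.shape != expected:
            raise ValueError(
                f"incidence shape {self.incidence.shape} does not match "
                f"(chaperones, clients, layers) = {expected}"
            )

    @property
    def n_chaperones(self) -> int:
        return len(self.chaperone_ids)

    @property
    def n_clients(self) -> int:
        return len(self.client_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layer_ids)

    def layer(self, layer_id: str) -> np.ndarray:
        """Return one layer's chaperone × client incidence matrix."""
        return self.incidence[:, :, self.layer_ids.index(layer_id)]

    def subset_layers(self, layer_ids: list[str]) -> "MultilayerNetwork":
        idx = [self.layer_ids.index(l) for l in layer_ids]
        return MultilayerNetwork(
            chaperone_ids=list(self.chaperone_ids),
            client_ids=list(self.client_ids),
            layer_ids=list(layer_ids),
            incidence=self.incidence[:, :, idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultilayerNetwork):
            return NotImplemented
        return (
            self.chaperone_ids == other.chaperone_ids
            and self.client_ids == other.client_ids
            and self.layer_ids == other.layer_ids
            and np.array_equal(self.incidence, other.incidence)
        )


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix (FPKM-like, unitless) for one environment."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    layer_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ValidationReport:
    """Accumulated invariant violations; empty == valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok


def _read_edge_list(path: Path) -> list[tuple[str, str]]:
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dup = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and header.strip() and len(header.rstrip("\n").split("\t")) != 2:
            raise ValueError(f"{path}: line 1: expected two tab-separated header fields")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: line {lineno}: malformed edge row {line!r}")
            e = (parts[0], parts[1])
            if e in seen:
                dup += 1
                continue
            seen.add(e)
            edges.append(e)
    if dup:
        warnings.warn(f"{path}: {dup} duplicate edge row(s) removed", stacklevel=3)
    return edges


def read_network_layers(directory_path: str | Path, manifest: str | Path | dict) -> MultilayerNetwork:
    """Load a multilayer network from per-layer TSV edge lists.

    ``manifest`` is a YAML file (or pre-parsed mapping) with a ``layers`` list
    of ``{layer_id: filename}`` entries fixing layer order; optional
    ``chaperones``/``clients`` lists pin the node sets (otherwise the union of
    identifiers across files defines them). Node ordering is lexicographic,
    so eigenvalues and EM initialisation are reproducible across platforms.
    """
    directory_path = Path(directory_path)
    if not isinstance(manifest, dict):
        with open(directory_path / manifest if not Path(manifest).is_absolute() else manifest) as fh:
            manifest = yaml.safe_load(fh)
    layer_entries: list[tuple[str, str]] = []
    for entry in manifest["layers"]:
        ((lid, fname),) = entry.items()
        layer_entries.append((str(lid), fname))

    per_layer_edges: dict[str, list[tuple[str, str]]] = {}
    chaps: set[str] = set(manifest.get("chaperones") or [])
    clients: set[str] = set(manifest.get("clients") or [])
    for lid, fname in layer_entries:
        edges = _read_edge_list(directory_path / fname)
        if not edges:
            warnings.warn(f"layer {lid!r}: empty edge list, layer is all zeros", stacklevel=2)
        per_layer_edges[lid] = edges
        chaps.update(e[0] for e in edges)
        clients.update(e[1] for e in edges)

    chaperone_ids = sorted(chaps)
    client_ids = sorted(clients)
    layer_ids = [lid for lid, _ in layer_entries]
    ci = {c: i for i, c in enumerate(chaperone_ids)}
    pi = {p: j for j, p in enumerate(client_ids)}
    incidence = np.zeros((len(chaperone_ids), len(client_ids), len(layer_ids)), dtype=np.int8)
    for a, lid in enumerate(layer_ids):
        for c, p in per_layer_edges[lid]:
            incidence[ci[c], pi[p], a] = 1
    return MultilayerNetwork(chaperone_ids, client_ids, layer_ids, incidence)


def write_network_layers(net: MultilayerNetwork, directory_path: str | Path) -> list[Path]:
    """Write one TSV edge list per layer plus a ``manifest.yaml``.

    Round-trips bit-exactly through :func:`read_network_layers`.
    """
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    entries = []
    for a, lid in enumerate(net.layer_ids):
        fname = f"layer_{lid}.tsv"
        entries.append({lid: fname})
        path = directory_path / fname
        rows, cols = np.nonzero(net.incidence[:, :, a])
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("chaperone\tclient\n")
            for i, j in zip(rows, cols):
                fh.write(f"{net.chaperone_ids[i]}\t{net.client_ids[j]}\n")
        written.append(path)
    manifest = {
        "layers": entries,
        "chaperones": list(net.chaperone_ids),
        "clients": list(net.client_ids),
    }
    with open(directory_path / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return written


def read_expression(path: str | Path, layer_id: str = "") -> ExpressionMatrix:
    """Read a genes × samples CSV (first column = gene id, header = sample ids)."""
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicated gene identifiers")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        layer_id=layer_id or Path(path).stem,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.to_frame().to_csv(path)
    return path


def validate_layer_frames(frames: dict[str, pd.DataFrame]) -> ValidationReport:
    """Check that per-layer chaperone × client DataFrames are mutually aligned.

    Layers must share identical row and column orderings before they can be
    stacked into a :class:`MultilayerNetwork`.
    """
    report = ValidationReport()
    ref_lid = next(iter(frames))
    ref = frames[ref_lid]
    for lid, df in frames.items():
        if list(df.index) != list(ref.index):
            report.violations.append(f"layer {lid!r}: chaperone ordering differs from layer {ref_lid!r}")
        if list(df.columns) != list(ref.columns):
            report.violations.append(f"layer {lid!r}: client ordering differs from layer {ref_lid!r}")
    return report


def validate_multilayer(net: MultilayerNetwork | dict[str, pd.DataFrame]) -> ValidationReport:
    """Report violated invariants; an empty report means the network is valid.

    Accepts either a built network or a mapping of per-layer DataFrames
    (the latter adds the cross-layer alignment check).
    """
    if isinstance(net, dict):
        report = validate_layer_frames(net)
        for lid, df in net.items():
            vals = np.unique(df.to_numpy())
            if not np.all(np.isin(vals, [0, 1])):
                bad = [v for v in vals.tolist() if v not in (0, 1)]
                report.violations.append(f"layer {lid!r}: non-binary entries: {bad}")
        return report
    report = ValidationReport()
    if len(set(net.chaperone_ids)) != len(net.chaperone_ids):
        report.violations.append("duplicate chaperone identifiers")
    if len(set(net.client_ids)) != len(net.client_ids):
        report.violations.append("duplicate client identifiers")
    if len(set(net.layer_ids)) != len(net.layer_ids):
        report.violations.append("duplicate layer identifiers")
    vals = np.unique(net.incidence)
    if not np.all(np.isin(vals, [0, 1])):
        bad = [v for v in vals.tolist() if v not in (0, 1)]
        report.violations.append(f"non-binary incidence entries: {bad}")
    return report
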