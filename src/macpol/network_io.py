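"""Plain-text signed edge-list format for regulatory networks.

The format is line-oriented, tab-separated, UTF-8:

* comment lines start with ``#`` and are ignored on load;
* ``node<TAB>NAME<TAB>ROLE<TAB>PHENOTYPE`` declares a node (in state-vector
  order) with role ``input``/``receptor``/``internal`` and phenotype branch
  ``M1``/``M2``;
* ``marker<TAB>PHENOTYPE<TAB>NAME`` names the marker gene whose activity
  identifies the committed attractor of that branch;
* every remaining line is one interaction, ``SOURCE<TAB>SIGN<TAB>TARGET``
  with sign ``+`` (activation) or ``-`` (inhibition).

The writer emits a canonical form (nodes, markers, then edges in node order)
that round-trips bit-exactly through the loader; the bundled default file is
itself writer output.
"""
from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

from .errors import NetworkFormatError
from .grn import RegulatoryNetwork

_HEADER = "# Signed Boolean regulatory network (macpol edge-list format v1)\n"

DEFAULT_NETWORK_RESOURCE = "macrophage_grn.tsv"


def load_network(path_or_text: str | Path, *, is_text: bool = False) -> RegulatoryNetwork:
    """Load and validate a network from a file path (or raw text).

    Raises :class:`NetworkFormatError` for an empty file, unknown nodes in
    edges, duplicate edges with conflicting signs, or malformed lines.
    """
    if is_text:
        text = str(path_or_text)
    else:
        text = Path(path_or_text).read_text(encoding="utf-8")
    nodes: list[str] = []
    roles: dict[str, str] = {}
    phenotype: dict[str, str] = {}
    markers: dict[str, str] = {}
    activators: dict[str, set[str]] = {}
    inhibitors: dict[str, set[str]] = {}
    seen_edges: dict[tuple[str, str], str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "node":
            if len(parts) != 4:
                raise NetworkFormatError(f"line {lineno}: node line needs 4 fields, got {len(parts)}")
            _, name, role, phen = parts
            if name in roles:
                raise NetworkFormatError(f"line {lineno}: duplicate node {name!r}")
            if role not in ("input", "receptor", "internal"):
                raise NetworkFormatError(f"line {lineno}: unknown role {role!r}")
            if phen not in ("M1", "M2"):
                raise NetworkFormatError(f"line {lineno}: unknown phenotype {phen!r}")
            nodes.append(name)
            roles[name] = role
            phenotype[name] = phen
        elif parts[0] == "marker":
            if len(parts) != 3:
                raise NetworkFormatError(f"line {lineno}: marker line needs 3 fields")
            _, phen, name = parts
            markers[phen] = name
        else:
            if len(parts) != 3:
                raise NetworkFormatError(
                    f"line {lineno}: edge line needs 'source<TAB>sign<TAB>target', got {line!r}"
                )
            src, sign, dst = parts
            if sign not in ("+", "-"):
                raise NetworkFormatError(f"line {lineno}: sign must be '+' or '-', got {sign!r}")
            for name in (src, dst):
                if name not in roles:
                    raise NetworkFormatError(f"line {lineno}: unknown node {name!r} in edge")
            prev = seen_edges.get((src, dst))
            if prev is not None and prev != sign:
                raise NetworkFormatError(
                    f"line {lineno}: edge {src}->{dst} appears with conflicting signs"
                )
            seen_edges[(src, dst)] = sign
            target_map = activators if sign == "+" else inhibitors
            target_map.setdefault(dst, set()).add(src)
    if not nodes:
        raise NetworkFormatError("no node declarations found (empty or comment-only file)")
    return RegulatoryNetwork(
        nodes=tuple(nodes),
        roles=roles,
        phenotype=phenotype,
        activators={k: frozenset(v) for k, v in activators.items()},
        inhibitors={k: frozenset(v) for k, v in inhibitors.items()},
        markers=markers,
    )


def network_to_text(net: RegulatoryNetwork) -> str:
    """Canonical serialization; ``load_network(network_to_text(net))`` == net."""
    lines = [_HEADER.rstrip("\n")]
    for name in net.nodes:
        lines.append(f"node\t{name}\t{net.roles.get(name, 'internal')}\t{net.phenotype.get(name, 'M1')}")
    for phen in ("M1", "M2"):
        lines.append(f"marker\t{phen}\t{net.markers[phen]}")
    order = {n: i for i, n in enumerate(net.nodes)}
    edges: list[tuple[int, int, str]] = []
    for dst, parents in net.activators.items():
        edges.extend((order[src], order[dst], "+") for src in parents)
    for dst, parents in net.inhibitors.items():
        edges.extend((order[src], order[dst], "-") for src in parents)
    for si, di, sign in sorted(edges):
        lines.append(f"{net.nodes[si]}\t{sign}\t{net.nodes[di]}")
    return "\n".join(lines) + "\n"


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    Path(path).write_text(network_to_text(net), encoding="utf-8")


def network_hash(net: RegulatoryNetwork) -> str:
    return hashlib.sha256(network_to_text(net).encode("utf-8")).hexdigest()


def default_network_text() -> str:
    return (resources.files("macpol") / "data" / DEFAULT_NETWORK_RESOURCE).read_text("utf-8")


def load_default_network() -> RegulatoryNetwork:
    """The bundled 18-node macrophage polarization network."""
    return load_network(default_network_text(), is_text=True)
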