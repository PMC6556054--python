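"""Flat-file bundle readers/writers, compound-set tables, and route output.

A network bundle is a directory with a ``manifest.json`` naming five files:

* ``compounds.tsv`` — columns ``id``, ``name``, ``atoms`` (comma-separated
  heavy-atom element symbols, order significant);
* ``reactions.tsv`` — ``id``, ``substrates``, ``products`` (comma-separated
  compound ids), ``reversible`` (true/false);
* ``organisms.tsv`` — ``id``, ``name``, ``tags`` (comma-separated, may be
  empty);
* ``org_reactions.tsv`` — sparse presence pairs ``org_id``, ``reaction_id``;
* ``atom_maps.json`` — records ``{"reaction", "substrate", "product",
  "pairs": [[i, j], ...]}``.

Compound-set tables are single-purpose TSVs whose first column lists
compound identifiers (extra columns are ignored); they serve as start or
goal metabolite sets.  Route results are written as JSON or Graphviz DOT.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

from .errors import BundleFormatError, EmptySelectionError
from .model import AtomMap, Compound, Reaction, RouteDB, build_db
from .orgsets import Organism, OrganismMatrix
from .search import Route

__all__ = [
    "BUNDLE_FORMAT",
    "BUNDLE_VERSION",
    "read_bundle",
    "write_bundle",
    "read_compound_table",
    "read_smarttable",
    "central_metabolism_table_path",
    "write_routes",
    "routes_payload",
    "render_route_dot",
]

BUNDLE_FORMAT = "orgroutes-bundle"
BUNDLE_VERSION = "1"

_FILES = {
    "compounds": "compounds.tsv",
    "reactions": "reactions.tsv",
    "organisms": "organisms.tsv",
    "org_reactions": "org_reactions.tsv",
    "atom_maps": "atom_maps.json",
}

#: Identifier syntax for compound-table cells; anything else (or embedded
#: whitespace) in the first data cell marks that row as a header.
_ID_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9_.+:\-]*$")


# ---------------------------------------------------------------------------
# bundle reading


def _read_tsv(path: Path, required: Sequence[str]) -> list[tuple[int, dict[str, str]]]:
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                raise BundleFormatError(f"{path}: empty file")
            missing = [c for c in required if c not in reader.fieldnames]
            if missing:
                raise BundleFormatError(f"{path}: missing columns {missing}")
            rows = []
            for lineno, row in enumerate(reader, start=2):
                for col in required:
                    if row.get(col) is None:
                        raise BundleFormatError(f"{path}:{lineno}: short row")
                rows.append((lineno, row))
            return rows
    except OSError as exc:
        raise BundleFormatError(f"{path}: {exc}") from exc


def _split(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    return tuple(part.strip() for part in cell.split(",") if part.strip()) if cell else ()


def _parse_bool(path: Path, lineno: int, cell: str) -> bool:
    low = cell.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no", ""}:
        return False
    raise BundleFormatError(f"{path}:{lineno}: bad boolean {cell!r}")


def read_bundle(path: str | Path) -> RouteDB:
    """Load and fully validate a bundle from a directory or manifest path."""
    p = Path(path)
    manifest_path = p / "manifest.json" if p.is_dir() else p
    try:
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise BundleFormatError(f"{manifest_path}: {exc}") from exc
    if manifest.get("format") != BUNDLE_FORMAT:
        raise BundleFormatError(
            f"{manifest_path}: unrecognized format {manifest.get('format')!r}"
        )
    if manifest.get("version") != BUNDLE_VERSION:
        raise BundleFormatError(
            f"{manifest_path}: unrecognized version {manifest.get('version')!r}"
        )
    files = manifest.get("files", {})
    base = manifest_path.parent
    paths = {}
    for key, default in _FILES.items():
        paths[key] = base / files.get(key, default)
        if not paths[key].exists():
            raise BundleFormatError(f"{paths[key]}: referenced file missing")

    compounds = [
        Compound(row["id"], row["name"], _split(row["atoms"]))
        for _, row in _read_tsv(paths["compounds"], ["id", "name", "atoms"])
    ]
    reactions = [
        Reaction(
            row["id"],
            _split(row["substrates"]),
            _split(row["products"]),
            _parse_bool(paths["reactions"], lineno, row["reversible"]),
        )
        for lineno, row in _read_tsv(
            paths["reactions"], ["id", "substrates", "products", "reversible"]
        )
    ]
    organisms = [
        Organism(row["id"], row["name"], _split(row["tags"]))
        for _, row in _read_tsv(paths["organisms"], ["id", "name", "tags"])
    ]
    membership: dict[str, list[str]] = {}
    for _, row in _read_tsv(paths["org_reactions"], ["org_id", "reaction_id"]):
        membership.setdefault(row["reaction_id"], []).append(row["org_id"])

    try:
        with open(paths["atom_maps"], encoding="utf-8") as fh:
            raw_maps = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise BundleFormatError(f"{paths['atom_maps']}: {exc}") from exc
    atom_maps = []
    for rec in raw_maps:
        try:
            atom_maps.append(
                AtomMap(
                    rec["reaction"],
                    rec["substrate"],
                    rec["product"],
                    tuple((int(i), int(j)) for i, j in rec["pairs"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise BundleFormatError(
                f"{paths['atom_maps']}: malformed record {rec!r}"
            ) from exc

    matrix = OrganismMatrix.from_membership(organisms, membership)
    return build_db(compounds, reactions, atom_maps, matrix)


# ---------------------------------------------------------------------------
# bundle writing


def write_bundle(db: RouteDB, out_dir: str | Path) -> Path:
    """Serialize a database to a bundle directory; returns the manifest path.

    Rows are written in sorted-id order so identical databases produce
    byte-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def tsv(name: str, header: list[str], rows: Iterable[list[str]]) -> None:
        with open(out / name, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    tsv(
        _FILES["compounds"],
        ["id", "name", "atoms"],
        [
            [c.id, c.name, ",".join(c.atoms)]
            for c in sorted(db.compounds.values(), key=lambda c: c.id)
        ],
    )
    tsv(
        _FILES["reactions"],
        ["id", "substrates", "products", "reversible"],
        [
            [r.id, ",".join(r.substrates), ",".join(r.products), str(r.reversible).lower()]
            for r in sorted(db.reactions.values(), key=lambda r: r.id)
        ],
    )
    matrix = db.org_matrix
    tsv(
        _FILES["organisms"],
        ["id", "name", "tags"],
        [[o.id, o.name, ",".join(o.tags)] for o in matrix.organisms],
    )
    pairs = []
    for rid in matrix.reaction_ids:
        for idx in matrix.row(rid).indices():
            pairs.append([matrix.organism_at(idx).id, rid])
    tsv(_FILES["org_reactions"], ["org_id", "reaction_id"], sorted(pairs))

    records = [
        {
            "reaction": am.reaction_id,
            "substrate": am.substrate_id,
            "product": am.product_id,
            "pairs": [list(p) for p in am.pairs],
        }
        for am in sorted(
            db.atom_maps.values(),
            key=lambda m: (m.reaction_id, m.substrate_id, m.product_id),
        )
    ]
    with open(out / _FILES["atom_maps"], "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")

    manifest = {"format": BUNDLE_FORMAT, "version": BUNDLE_VERSION, "files": _FILES}
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest_path


# ---------------------------------------------------------------------------
# compound-set tables


def read_compound_table(
    path: str | Path,
    db: RouteDB | None = None,
    *,
    header: bool | None = None,
) -> list[str]:
    """Read a compound set from the first column of a TSV table.

    The first row is treated as a header when ``header`` is True, or (when
    ``header`` is None) when its first cell contains whitespace or is not a
    well-formed identifier.  Duplicates are removed keeping first occurrence.
    If ``db`` is given, at least one id must resolve against it.
    """
    p = Path(path)
    with open(p, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row and row[0].strip()]
    if not rows:
        raise BundleFormatError(f"{p}: compound table is empty")
    first = rows[0][0].strip()
    skip_first = header if header is not None else not _ID_RE.match(first)
    ids: list[str] = []
    seen: set[str] = set()
    for row in rows[1:] if skip_first else rows:
        cid = row[0].strip()
        if cid not in seen:
            seen.add(cid)
            ids.append(cid)
    if not ids:
        raise BundleFormatError(f"{p}: compound table has no data rows")
    if db is not None and not any(cid in db.compounds for cid in ids):
        raise EmptySelectionError(f"{p}: no listed compound resolves against the database")
    return ids


#: Alias matching the field's name for these single-column stored tables.
read_smarttable = read_compound_table


def central_metabolism_table_path() -> Path:
    """Path to the packaged compound set of 13 common central-metabolism
    intermediates (useful default start or goal set)."""
    return Path(__file__).parent / "data" / "central_metabolism.tsv"


# ---------------------------------------------------------------------------
# route output


def _org_names(matrix, orgs) -> list[str]:
    return [matrix.organism_at(i).name for i in orgs.indices()]


def routes_payload(routes: Sequence[Route], status: str, matrix) -> dict:
    """JSON-ready representation of ranked routes.

    Per step, the organism count is always given; names are listed only when
    there are at most 10 organisms.
    """
    out_routes = []
    for rank, route in enumerate(routes, start=1):
        steps = []
        for arc, orgs in zip(route.steps, route.step_orgs):
            n = orgs.popcount()
            steps.append(
                {
                    "reaction": arc.reaction_id,
                    "from": arc.from_compound,
                    "to": arc.to_compound,
                    "organism_count": n,
                    "organisms": sorted(_org_names(matrix, orgs)) if n <= 10 else None,
                }
            )
        segments = [
            {
                "organisms": sorted(matrix.organism_at(i).id for i in seg.organisms.indices()),
                "reactions": list(seg.reactions),
            }
            for seg in route.segments
        ]
        out_routes.append(
            {
                "rank": rank,
                "start": route.start_compound,
                "end": route.end_compound,
                "reactions": list(route.reaction_ids),
                "intermediates": list(route.compound_chain),
                "conserved_atoms": route.conserved_atoms,
                "atoms_lost": route.atoms_lost,
                "switches": route.switches,
                "switch_minimized": route.switch_minimized,
                "cost": {
                    "total": route.cost.total,
                    "reactions": route.cost.reactions,
                    "atoms_lost": route.cost.atoms_lost,
                    "switches": route.cost.switches,
                },
                "steps": steps,
                "segments": segments,
            }
        )
    return {"status": status, "n_routes": len(routes), "routes": out_routes}


def write_routes(
    routes: Sequence[Route],
    status: str,
    path: str | Path,
    format: str = "json",
    *,
    matrix=None,
) -> None:
    """Write ranked routes to ``path`` as JSON or DOT."""
    if matrix is None:
        raise ValueError("write_routes requires the organism matrix for annotation")
    p = Path(path)
    if format == "json":
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(routes_payload(routes, status, matrix), fh, indent=2)
            fh.write("\n")
    elif format == "dot":
        text = "\n".join(
            render_route_dot(route, matrix, name=f"route_{i}")
            for i, route in enumerate(routes, start=1)
        )
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    else:
        raise ValueError(f"unknown output format {format!r}")


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def render_route_dot(route: Route, matrix, *, name: str = "route") -> str:
    """Render one route as Graphviz DOT: compounds as nodes, reactions as
    labeled edges.  When switch minimization was on, the first edge of every
    new organism segment is marked ``[organism switch]`` and drawn red."""
    switch_steps: set[int] = set()
    if route.switch_minimized:
        idx = 0
        for seg_no, seg in enumerate(route.segments):
            if seg_no > 0:
                switch_steps.add(idx)
            idx += len(seg.reactions)
    lines = [f"digraph {name} {{", "  rankdir=LR;", "  node [shape=box];"]
    for cid in route.compound_chain:
        lines.append(f"  {_dot_quote(cid)};")
    for i, (arc, orgs) in enumerate(zip(route.steps, route.step_orgs)):
        label = f"{arc.reaction_id} ({orgs.popcount()} organisms)"
        attrs = [f"label={_dot_quote(label)}"]
        if i in switch_steps:
            attrs[0] = f"label={_dot_quote(label + ' [organism switch]')}"
            attrs.append('color="red"')
        lines.append(
            f"  {_dot_quote(arc.from_compound)} -> {_dot_quote(arc.to_compound)} "
            f"[{', '.join(attrs)}];"
        )
    lines.append("}")
    return "\n".join(lines)
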