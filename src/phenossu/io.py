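"""Readers and writers: brat standoff, JSON-lines instances, motif text.

All offsets are 0-based half-open in Unicode code points, matching brat's
standoff conventions and the encoder's spans.  Every writer/reader pair is
a round trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import ALPHABET
from .motifs import Motif
from .recognize import PhenoSSUInstance
from .schema import PhenoSSUSchema, default_schema

logger = logging.getLogger(__name__)

INSTANCES_HEADER = "# phenossu instances v1"


class BratError(ValueError):
    """A .ann file is inconsistent with its text."""


@dataclass
class BratDocument:
    text: str
    entities: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    # entity: (id, type, start, end, surface)
    attributes: list[tuple[str, str, str, str]] = field(default_factory=list)
    # attribute: (id, name, entity id, value)
    doc_id: str | None = None


def read_brat(txt_path: str | Path, ann_path: str | Path) -> BratDocument:
    """Parse a brat .txt/.ann pair (T entity lines, A attribute lines)."""
    text = Path(txt_path).read_text("utf-8")
    doc = BratDocument(text=text, doc_id=Path(txt_path).stem)
    entity_ids = set()
    for lineno, line in enumerate(Path(ann_path).read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            try:
                eid, middle, surface = line.split("\t", 2)
                etype, start, end = middle.split(" ")
                start, end = int(start), int(end)
            except ValueError:
                raise BratError(f"{ann_path}:{lineno}: malformed T line") from None
            if text[start:end] != surface:
                raise BratError(
                    f"{ann_path}: entity {eid}: surface {surface!r} does not equal "
                    f"text[{start}:{end}] = {text[start:end]!r}"
                )
            doc.entities.append((eid, etype, start, end, surface))
            entity_ids.add(eid)
        elif line.startswith("A"):
            try:
                aid, rest = line.split("\t", 1)
                name, target, value = rest.split(" ", 2)
            except ValueError:
                raise BratError(f"{ann_path}:{lineno}: malformed A line") from None
            doc.attributes.append((aid, name, target, value))
        else:
            logger.warning("%s:%d: unknown line type skipped", ann_path, lineno)
    for _, _, target, _ in doc.attributes:
        if target not in entity_ids:
            raise BratError(f"{ann_path}: attribute refers to unknown entity {target}")
    return doc


def write_brat(doc: BratDocument, txt_path: str | Path, ann_path: str | Path) -> None:
    Path(txt_path).write_text(doc.text, "utf-8")
    lines = [
        f"{eid}\t{etype} {start} {end}\t{surface}"
        for eid, etype, start, end, surface in doc.entities
    ]
    lines += [f"{aid}\t{name} {target} {value}" for aid, name, target, value in doc.attributes]
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""), "utf-8")


_ATTR_TYPE = {
    "assertion": "Assertion",
    "severity": "Severity",
    "temporal pattern": "Temporal_pattern",
    "laterality": "Laterality",
    "spatial pattern": "Spatial_pattern",
    "quadrant pattern": "Quadrant_pattern",
    "body location": "Body_location",
    "specimen": "Specimen",
    "analyte": "Analyte",
    "abnormality": "Abnormality",
}
_TYPE_ATTR = {v: k for k, v in _ATTR_TYPE.items()}


def instances_to_brat(
    text: str,
    instances: list[PhenoSSUInstance],
    entities: list[tuple[str, int, int]] | None = None,
    doc_id: str | None = None,
) -> BratDocument:
    """Serialize instances (plus optional extra trigger entities) as brat."""
    doc = BratDocument(text=text, doc_id=doc_id)
    counter = 0
    by_span: dict[tuple, str] = {}

    def add_entity(etype: str, start: int, end: int) -> str:
        nonlocal counter
        key = (etype, start, end)
        if key in by_span:
            return by_span[key]
        counter += 1
        eid = f"T{counter}"
        doc.entities.append((eid, etype, start, end, text[start:end]))
        by_span[key] = eid
        return eid

    for etype, start, end in entities or []:
        add_entity(etype, start, end)
    n_attr = 0
    for inst in instances:
        if inst.phenotype_span is None:
            continue
        etype = "Phenotype" if inst.category == "phrase-based" else "Analyte"
        eid = add_entity(etype, *inst.phenotype_span)
        for name, (value, _) in sorted(inst.attributes.items()):
            n_attr += 1
            doc.attributes.append(
                (f"A{n_attr}", _ATTR_TYPE.get(name, name), eid, value)
            )
    return doc


def brat_to_instances(doc: BratDocument) -> list[PhenoSSUInstance]:
    """Reconstruct gold instances from a brat document (anchor entities are
    Phenotype for phrase-based and Analyte for logic-based)."""
    by_id = {eid: (etype, start, end) for eid, etype, start, end, _ in doc.entities}
    attrs_by_target: dict[str, dict[str, str]] = {}
    for _, name, target, value in doc.attributes:
        attrs_by_target.setdefault(target, {})[_TYPE_ATTR.get(name, name)] = value
    instances = []
    for eid, etype, start, end, surface in doc.entities:
        if etype not in ("Phenotype", "Analyte"):
            continue
        attrs = attrs_by_target.get(eid, {})
        if etype == "Analyte" and not attrs:
            continue  # a bare analyte trigger, not an instance anchor
        category = "phrase-based" if etype == "Phenotype" else "logic-based"
        attributes = {k: (v, None) for k, v in attrs.items()}
        if category == "phrase-based" and "assertion" not in attributes:
            attributes["assertion"] = ("present", None)
        phenotype = surface
        if category == "logic-based":
            phenotype = f"{attrs.get('analyte', surface)} {attrs.get('abnormality', '')}".strip()
        instances.append(
            PhenoSSUInstance(
                phenotype=phenotype,
                phenotype_span=(start, end),
                attributes=attributes,
                category=category,
                doc_id=doc.doc_id,
            )
        )
    instances.sort(key=lambda x: (x.phenotype_span or (0, 0), x.phenotype))
    return instances


# ---------------------------------------------------------------------------
# JSON-lines instances


def write_instances(
    instances: list[PhenoSSUInstance],
    path: str | Path,
    schema: PhenoSSUSchema | None = None,
) -> None:
    """Write instances as schema-validated JSON lines (one per line)."""
    schema = schema if schema is not None else default_schema()
    for inst in instances:
        inst.validate_against(schema)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(INSTANCES_HEADER + "\n")
        for inst in instances:
            fh.write(json.dumps(_instance_to_json(inst), ensure_ascii=False) + "\n")


def _instance_to_json(inst: PhenoSSUInstance) -> dict:
    return {
        "doc_id": inst.doc_id,
        "phenotype": inst.phenotype,
        "phenotype_span": list(inst.phenotype_span) if inst.phenotype_span else None,
        "category": inst.category,
        "snomed": inst.snomed,
        "pattern": inst.pattern,
        "attributes": {
            name: {"value": value, "span": list(span) if span else None}
            for name, (value, span) in sorted(inst.attributes.items())
        },
    }


def _instance_from_json(obj: dict) -> PhenoSSUInstance:
    return PhenoSSUInstance(
        phenotype=obj["phenotype"],
        phenotype_span=tuple(obj["phenotype_span"]) if obj.get("phenotype_span") else None,
        attributes={
            name: (entry["value"], tuple(entry["span"]) if entry.get("span") else None)
            for name, entry in obj.get("attributes", {}).items()
        },
        category=obj.get("category", "phrase-based"),
        snomed=obj.get("snomed"),
        pattern=obj.get("pattern"),
        doc_id=obj.get("doc_id"),
    )


def read_instances(path: str | Path) -> list[PhenoSSUInstance]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(_instance_from_json(json.loads(line)))
    return out


# ---------------------------------------------------------------------------
# motif text format (MEME-like minimal) and JSON


def write_motifs(motifs: list[Motif], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ALPHABET {ALPHABET}\n\n")
        for i, m in enumerate(motifs, 1):
            fh.write(f"MOTIF m{i} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= {len(ALPHABET)} w= {m.width} "
                f"nsites= {m.nsites} E= {m.evalue:.6g} llr= {m.llr:.6g} "
                f"lambda= {m.lam:.6g}\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_motifs(path: str | Path) -> list[Motif]:
    motifs = []
    lines = Path(path).read_text("utf-8").splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("MOTIF"):
            consensus = line.split()[2]
            header = lines[i + 1]
            fields = dict(
                (k.rstrip("="), v)
                for k, v in zip(header.split()[2::2], header.split()[3::2])
            )
            w = int(fields["w"])
            pwm = np.array(
                [[float(x) for x in lines[i + 2 + r].split()] for r in range(w)]
            )
            motifs.append(
                Motif(
                    width=w,
                    pwm=pwm,
                    lam=float(fields["lambda"]),
                    sites=[],
                    llr=float(fields["llr"]),
                    consensus=consensus,
                    evalue=float(fields["E"]),
                )
            )
            i += 2 + w
        else:
            i += 1
    return motifs


def motifs_to_json(motifs: list[Motif]) -> list[dict]:
    return [
        {
            "consensus": m.consensus,
            "width": m.width,
            "nsites": m.nsites,
            "evalue": m.evalue,
            "llr": m.llr,
            "lambda": m.lam,
            "pwm": [[round(float(p), 6) for p in row] for row in m.pwm],
            "sites": [[int(s), int(o), round(float(z), 4)] for s, o, z in m.sites],
        }
        for m in motifs
    ]


# ---------------------------------------------------------------------------
# synthetic corpus on disk


def write_corpus(docs, outdir: str | Path, schema: PhenoSSUSchema | None = None) -> None:
    """Write a generated corpus as brat .txt/.ann pairs plus gold.jsonl."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_instances = []
    for doc in docs:
        brat = instances_to_brat(doc.text, doc.instances, doc.entities, doc_id=doc.doc_id)
        write_brat(brat, outdir / f"{doc.doc_id}.txt", outdir / f"{doc.doc_id}.ann")
        all_instances.extend(doc.instances)
    write_instances(all_instances, outdir / "gold.jsonl", schema=schema)


def read_corpus_texts(indir: str | Path) -> dict[str, str]:
    return {
        p.stem: p.read_text("utf-8") for p in sorted(Path(indir).glob("*.txt"))
    }
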