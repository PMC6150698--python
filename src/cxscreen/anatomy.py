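"""Cell-type nomenclature parsing and anatomical-overlap labelling.

Central-complex cell types are named by their innervated regions with
polarity suffixes: ``.s`` marks spiny (postsynaptic-looking, input) arbors
and ``.b`` bouton (presynaptic-looking, output) arbors, e.g.
``PBG2-9.s-FBl3.b-NO2D.b`` — spiny in protocerebral-bridge glomeruli 2–9,
boutons in fan-shaped-body layer 3 and in the dorsal-posterior nodulus 2.

A candidate pair (pre, post) is *anatomically overlapping* when some region
where the presynaptic type has boutons intersects a region where the
postsynaptic type has spines.  Intersection is evaluated at the resolution
of the individual glomerulus for the PB, the layer for the FB, and the
individual nodulus for the NO; other regions match by name, with an
unqualified token matching any qualified one (the permissive default — the
finer LAL-zone subdivision used for labelling is not part of the public
nomenclature, so undivided ``LAL`` counts any LAL–LAL contact as overlap
unless zone tokens are supplied).

Overlap is directional: ``overlap(A, B)`` asks whether A's boutons meet B's
spines, which generally differs from ``overlap(B, A)``.

Names with internal micro-structure that the grammar does not cover (the Δ7
interneuron, ring neurons and a few others) are registered as curated
special cases.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Region",
    "Arbor",
    "ArborAnnotation",
    "OverlapLabel",
    "parse_type_name",
    "format_annotation",
    "overlap",
    "load_catalog",
    "annotation_for",
    "overlap_matrix",
    "SPECIAL_ARBORS",
]

SPINY = "spiny"    # postsynaptic-looking (.s)
BOUTON = "bouton"  # presynaptic-looking (.b)

#: Known non-polarity token modifiers (variant / laterality markers).
_MODIFIERS = {"contra", "contra2", "Type1", "Type2"}

_PB_GLOMERULI = 18  # 9 per hemisphere


@dataclass(frozen=True)
class Region:
    """An anatomical region at the labelling resolution.

    ``family`` is the neuropil (PB, FB, NO, EB, LAL, GA, ...);
    ``glomeruli``/``layers`` carry the PB-glomerulus or FB-layer sets
    (``None`` = unspecified, matches any); ``qualifier`` carries
    sub-compartment labels for other regions (e.g. the nodulus "2D").
    """

    family: str
    glomeruli: frozenset[int] | None = None
    layers: frozenset[int] | None = None
    qualifier: str = ""

    def intersects(self, other: "Region") -> bool:
        if self.family != other.family:
            return False
        if self.family == "PB":
            if self.glomeruli is None or other.glomeruli is None:
                return True
            return bool(self.glomeruli & other.glomeruli)
        if self.family == "FB":
            if self.layers is None or other.layers is None:
                return True
            return bool(self.layers & other.layers)
        if self.family == "NO":
            # individual-nodulus resolution: number must match; an
            # unspecified sub-compartment matches any
            a, b = self.qualifier, other.qualifier
            if not a or not b:
                return a[:1] == b[:1] if a and b else True
            if a[0] != b[0]:
                return False
            sa, sb = a[1:], b[1:]
            return (not sa) or (not sb) or sa == sb
        # generic regions: unqualified matches any (permissive default)
        return (not self.qualifier) or (not other.qualifier) \
            or self.qualifier == other.qualifier

    def label(self) -> str:
        if self.family == "PB" and self.glomeruli is not None:
            g = sorted(self.glomeruli)
            if len(g) == _PB_GLOMERULI:
                return "PB18"
            return f"PBG{g[0]}-{g[-1]}" if len(g) > 1 else f"PBG{g[0]}"
        if self.family == "FB" and self.layers is not None:
            l = sorted(self.layers)
            return f"FBl{l[0]}" if len(l) == 1 else f"FBl{l[0]}-{l[-1]}"
        if self.family == "GA" and self.qualifier:
            if self.qualifier.endswith("surround"):
                return f"{self.qualifier[:-len('surround')]}_GAsurround"
            return f"{self.qualifier}_GA"
        return self.family + self.qualifier

    def intersection_label(self, other: "Region") -> str:
        """Label of the shared territory (assumes ``intersects(other)``)."""
        if self.family == "PB" and self.glomeruli and other.glomeruli:
            return Region("PB", glomeruli=self.glomeruli & other.glomeruli).label()
        if self.family == "FB" and self.layers and other.layers:
            return Region("FB", layers=self.layers & other.layers).label()
        return self.label() if self.qualifier else other.label()


@dataclass(frozen=True)
class Arbor:
    region: Region
    polarity: frozenset  # subset of {SPINY, BOUTON}

    def __post_init__(self) -> None:
        if not self.polarity:
            raise ValueError("an arbor needs at least one polarity")


@dataclass(frozen=True)
class ArborAnnotation:
    type_name: str
    arbors: tuple[Arbor, ...]

    def regions(self, polarity: str) -> list[Region]:
        return [a.region for a in self.arbors if polarity in a.polarity]

    def content(self) -> set[tuple[Region, str]]:
        """(region, polarity) pairs — the comparable content of a name."""
        return {(a.region, p) for a in self.arbors for p in sorted(a.polarity)}


@dataclass(frozen=True)
class OverlapLabel:
    pre_type: str
    post_type: str
    overlapping: bool
    shared_regions: tuple[str, ...]


def _arbor(family, pol, *, glomeruli=None, layers=None, qualifier=""):
    return Arbor(
        Region(family,
               glomeruli=None if glomeruli is None else frozenset(glomeruli),
               layers=None if layers is None else frozenset(layers),
               qualifier=qualifier),
        frozenset(pol))


#: Curated arbors for names the grammar does not cover.  The Δ7 interneuron
#: spans all 18 PB glomeruli with interleaved spiny and bouton micro-arbors;
#: ring-neuron names encode ring/annulus micro-structure.
SPECIAL_ARBORS: dict[str, tuple[Arbor, ...]] = {
    # Δ7: spiny and boutons across the full bridge
    "PB18.s-GxΔ7Gy.b-PB18.s-9i1i8c.b": (
        _arbor("PB", {SPINY, BOUTON}, glomeruli=range(1, _PB_GLOMERULI + 1)),
    ),
    # ring neurons: ellipsoid-body ring with mixed input/output, spines in
    # the lateral accessory lobe or bulb
    "EBIRP I-O-LAL.s": (
        _arbor("EB", {SPINY, BOUTON}, qualifier=""),
        _arbor("LAL", {SPINY}),
    ),
    "EBMRP I-O-LAL.s": (
        _arbor("EB", {SPINY, BOUTON}, qualifier=""),
        _arbor("LAL", {SPINY}),
    ),
    "EBORP O-I-GA-Bulb": (
        _arbor("EB", {SPINY, BOUTON}, qualifier=""),
        _arbor("GA", {SPINY, BOUTON}),
        _arbor("BU", {SPINY}),
    ),
    # EB input from the anterior medial protocerebrum via the Gall surround
    "EB.w-AMP.d-D_GAsurround": (
        _arbor("EB", {BOUTON}, qualifier=""),
        _arbor("AMP", {SPINY}),
        _arbor("GA", {SPINY}, qualifier="Dsurround"),
    ),
    "EBMRA-FB-LT-LT-GA-GA": (
        _arbor("EB", {SPINY, BOUTON}, qualifier=""),
        _arbor("FB", {SPINY, BOUTON}),
        _arbor("LT", {SPINY, BOUTON}),
        _arbor("GA", {SPINY, BOUTON}),
    ),
    "LAL-Cre": (
        _arbor("LAL", {SPINY, BOUTON}),
        _arbor("CRE", {SPINY, BOUTON}),
    ),
}


_RE_PB_RANGE = re.compile(r"^PBG(\d+)-(\d+)$")
_RE_PB_SINGLE = re.compile(r"^PBG(\d+)$")
_RE_PB_ALL = re.compile(r"^PB(\d+)$")
_RE_FB_LAYER = re.compile(r"^FBl(\d+)(?:-(\d+))?$")
_RE_NO = re.compile(r"^NO(\d)([A-Z]*)([ic]?)$")
_RE_EB = re.compile(r"^EB([a-z]?)$")
_RE_LAL = re.compile(r"^LAL(\d?)$")
_RE_GA = re.compile(r"^(?:([A-Z]+)_)?GA([a-z]?)(surround)?$")


def _parse_region(token: str) -> Region:
    """Map one region token to a :class:`Region` at labelling resolution."""
    if m := _RE_PB_RANGE.match(token):
        a, b = int(m[1]), int(m[2])
        if a > b or a < 1:
            raise ValueError(f"bad PB glomerulus range in token {token!r}")
        return Region("PB", glomeruli=frozenset(range(a, b + 1)))
    if m := _RE_PB_SINGLE.match(token):
        return Region("PB", glomeruli=frozenset({int(m[1])}))
    if m := _RE_PB_ALL.match(token):
        return Region("PB", glomeruli=frozenset(range(1, int(m[1]) + 1)))
    if token == "PB":
        return Region("PB")
    if m := _RE_FB_LAYER.match(token):
        a = int(m[1])
        b = int(m[2]) if m[2] else a
        return Region("FB", layers=frozenset(range(a, b + 1)))
    if token == "FB":
        return Region("FB")
    if m := _RE_NO.match(token):
        # laterality markers (i/c) are ignored for overlap
        return Region("NO", qualifier=m[1] + m[2])
    if m := _RE_EB.match(token):
        # wedge/tile tilings of the EB annulus are overlapping partitions,
        # so the EB is matched as a whole
        return Region("EB")
    if m := _RE_LAL.match(token):
        return Region("LAL", qualifier=m[1])
    if m := _RE_GA.match(token):
        prefix = m[1] or ""
        surround = m[3] or ""
        return Region("GA", qualifier=(prefix + surround) if surround else prefix)
    if re.fullmatch(r"[A-Za-z][A-Za-z_]*\d?", token):
        fam = token.upper() if token.islower() else token
        if fam in {"CRE", "Cre"}:
            fam = "CRE"
        if fam in {"WEDGE", "Wedge"}:
            fam = "WEDGE"
        return Region(fam)
    raise ValueError(f"unparseable region token {token!r}")


def _split_tokens(name: str) -> list[str]:
    """Split on hyphens except those inside numeric ranges (e.g. G2-9)."""
    tokens, buf = [], []
    for i, ch in enumerate(name):
        if ch == "-" and not (i > 0 and name[i - 1].isdigit()
                              and i + 1 < len(name) and name[i + 1].isdigit()):
            tokens.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    tokens.append("".join(buf))
    return [t for t in tokens if t]


def parse_type_name(name: str,
                    overrides: Mapping[str, tuple[Arbor, ...]] | None = None
                    ) -> ArborAnnotation:
    """Parse a type-description string into its arbors.

    ``overrides`` extends/replaces the curated special-case registry.
    Tokens without a polarity suffix inherit the nearest following token's
    polarity; if none follows, they are treated as mixed (both polarities).
    """
    if not name:
        raise ValueError("empty type name")
    registry = dict(SPECIAL_ARBORS)
    if overrides:
        registry.update(overrides)
    if name in registry:
        return ArborAnnotation(type_name=name, arbors=tuple(registry[name]))

    raw: list[tuple[str, set[str], list[str]]] = []  # (region token, polarities, modifiers)
    for token in _split_tokens(name):
        segments = token.split(".")
        current: list[tuple[str, set, list]] | None = None
        for seg in segments:
            if seg == "s" and current is not None:
                current[1].add(SPINY)
            elif seg == "b" and current is not None:
                current[1].add(BOUTON)
            elif seg in _MODIFIERS and current is not None:
                current[2].append(seg)
            else:
                current = (seg, set(), [])
                raw.append(current)
    if not raw:
        raise ValueError(f"no region tokens in {name!r}")

    # polarity inheritance from the nearest following suffixed token
    polarities: list[set[str]] = [set(p) for _, p, _ in raw]
    for i in range(len(raw) - 1, -1, -1):
        if not polarities[i]:
            nxt = next((polarities[j] for j in range(i + 1, len(raw))
                        if polarities[j]), None)
            polarities[i] = set(nxt) if nxt else {SPINY, BOUTON}

    arbors = []
    for (token, _, _), pol in zip(raw, polarities):
        region = _parse_region(token)
        arbors.append(Arbor(region=region, polarity=frozenset(pol)))
    return ArborAnnotation(type_name=name, arbors=tuple(arbors))


def format_annotation(annotation: ArborAnnotation) -> str:
    """Canonical string for an annotation; special-cased names keep their
    original spelling.  ``parse(format(parse(s)))`` preserves the
    region/polarity content of ``s``."""
    if annotation.type_name in SPECIAL_ARBORS:
        return annotation.type_name
    parts = []
    for arbor in annotation.arbors:
        suffix = "".join(
            f".{c}" for c, p in (("s", SPINY), ("b", BOUTON))
            if p in arbor.polarity)
        parts.append(arbor.region.label() + suffix)
    return "-".join(parts)


def overlap(pre: ArborAnnotation, post: ArborAnnotation) -> OverlapLabel:
    """Directional overlap call: do ``pre``'s boutons meet ``post``'s spines?"""
    shared = []
    for r_pre in pre.regions(BOUTON):
        for r_post in post.regions(SPINY):
            if r_pre.intersects(r_post):
                shared.append(r_pre.intersection_label(r_post))
    shared_unique = tuple(dict.fromkeys(shared))
    return OverlapLabel(pre_type=pre.type_name, post_type=post.type_name,
                        overlapping=bool(shared_unique),
                        shared_regions=shared_unique)


# ---------------------------------------------------------------------------
# Catalog: the screen's driver lines and cell types (driver, short name,
# type-description string).
# ---------------------------------------------------------------------------

_CATALOG_TSV = """\
driver	type_name	description
87G07	P-F3N2d	PBG2-9.s-FBl3.b-NO2D.b
85H06	P-F1N3	PBG2-9.s-FBl1.b-NO3PM.b
60D05	E-PG	PBG1-8.b-EBw.s-DV_GA.b
SS02191	P-EG	PBG1-8.s-EBt.b-DV_GA.b
67D09	P-F3N2v	PBG2-9.s-FBl3.b-NO2V.b
67D09-attP5	P-F3N2v	PBG2-9.s-FBl3.b-NO2V.b
67D09-VK22	P-F3N2v	PBG2-9.s-FBl3.b-NO2V.b
37F06	P-EN1	PBG2-9.s-EBt.b-NO1.b.Type1
37F06-VK22	P-EN1	PBG2-9.s-EBt.b-NO1.b.Type1
VT008135	P-EN1	PBG2-9.s-EBt.b-NO1.b.Type1
SS02232	P-EN2	PBG2-9.s-EBt.b-NO1.b.Type2
84H05	PF-LCre	PBG1-7.s-FBl2.s-LAL.b-cre.b
84H05-VK22	PF-LCre	PBG1-7.s-FBl2.s-LAL.b-cre.b
84H05-attP5	PF-LCre	PBG1-7.s-FBl2.s-LAL.b-cre.b
55G08	Δ7	PB18.s-GxΔ7Gy.b-PB18.s-9i1i8c.b
55G08-attP5	Δ7	PB18.s-GxΔ7Gy.b-PB18.s-9i1i8c.b
55G08-VK22	Δ7	PB18.s-GxΔ7Gy.b-PB18.s-9i1i8c.b
47G08	IS-P	PBG2-9.b-IB.s.SPS.s
49H05	IMPL-F	LAL.s-IMP-FBl3.b
75H04	L-Ei	EBIRP I-O-LAL.s
32A11	L-Em	EBMRP I-O-LAL.s
18A05	GB-Eo	EBORP O-I-GA-Bulb
18A05-VK22	GB-Eo	EBORP O-I-GA-Bulb
17H12	AMPG-E	EB.w-AMP.d-D_GAsurround
12C11	EFBG	EBMRA-FB-LT-LT-GA-GA
72H06	SMPL-L	SMP.s-LAL.s-LAL.b.contra
72H06-attP5	SMPL-L	SMP.s-LAL.s-LAL.b.contra
72H06-VK22	SMPL-L	SMP.s-LAL.s-LAL.b.contra
SS02615	SMPL-L2	SMP.s-LAL.s-LAL.b.contra2
26B07	WL-L	Wedge-LAL.s-LAL.b.contra
31A11	L-Cre	LAL-Cre
SS00153	S-P	SPS.s-PB.b
76E11	GL-N1	LAL.s-GAi.s-NO1i.b
76E11-VK22	GL-N1	LAL.s-GAi.s-NO1i.b
SS04448	GL-N1	LAL.s-GAi.s-NO1i.b
SS04420	CreL-N2	Cre.s-LAL.s-NO2.b
12G04	L-N3	LAL.s-NO3Ai.b
"""


def load_catalog(path: str | None = None) -> pd.DataFrame:
    """The cell-type catalog (driver, type_name, description).

    With ``path``, reads a user CSV with the same columns instead of the
    packaged screen catalog.
    """
    if path is not None:
        return pd.read_csv(path)
    return pd.read_csv(io.StringIO(_CATALOG_TSV), sep="\t")


def annotation_for(type_name: str,
                   catalog: pd.DataFrame | None = None) -> ArborAnnotation:
    """Parse the (unique) description of a short type name from the catalog."""
    cat = load_catalog() if catalog is None else catalog
    rows = cat[cat["type_name"] == type_name]
    if rows.empty:
        raise KeyError(f"unknown cell type {type_name!r}")
    descriptions = rows["description"].unique()
    if len(descriptions) > 1:
        raise ValueError(
            f"type {type_name!r} has conflicting descriptions {descriptions}")
    ann = parse_type_name(descriptions[0])
    return ArborAnnotation(type_name=type_name, arbors=ann.arbors)


def overlap_matrix(type_names: Iterable[str] | None = None,
                   catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Directional pre→post overlap matrix over the catalog's cell types."""
    cat = load_catalog() if catalog is None else catalog
    names = list(dict.fromkeys(type_names if type_names is not None
                               else cat["type_name"]))
    annotations = {n: annotation_for(n, cat) for n in names}
    data = [[overlap(annotations[a], annotations[b]).overlapping
             for b in names] for a in names]
    return pd.DataFrame(data, index=pd.Index(names, name="pre"),
                        columns=pd.Index(names, name="post"))
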