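"""Clinical-protocol templates, automation configuration and name matching.

The clinical protocol is an XML document (schema shipped in
``rtautoplan/data/clinical_protocol.xsd``) carrying the prescription, the
target, the templated treatment fields, the default machine and the clinical
goals. The automation config (YAML) carries what the protocol cannot:
structure-derivation rules, the knowledge-based-planning (KBP) model structure
map, target dose levels and algorithm-setting overrides. A structure
dictionary (XML) maps canonical structure names to institutional synonyms so
that template names can be located in structure sets that do not follow the
template nomenclature exactly.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field

import yaml
from lxml import etree

__all__ = [
    "MetricSpec",
    "ClinicalGoal",
    "FieldTemplate",
    "ClinicalProtocol",
    "DerivationStep",
    "DerivationRule",
    "AutomationConfig",
    "StructureDictionary",
    "MatchResult",
    "ProtocolError",
    "parse_clinical_protocol",
    "serialize_clinical_protocol",
    "parse_automation_config",
    "parse_structure_dictionary",
    "match_structure",
    "resolve_model_matches",
    "packaged_data_path",
]

_DOSE_TOL = 1e-6


class ProtocolError(ValueError):
    """A template, config or dictionary document violates its contract."""


def packaged_data_path(name: str):
    """Path to a packaged data file (protocol, config, dictionary, schema)."""
    return importlib.resources.files("rtautoplan") / "data" / name


# ---------------------------------------------------------------------------
# dose metrics specification
# ---------------------------------------------------------------------------

_METRIC_KINDS = ("D_percent", "D_cc", "V_gy", "D_min", "D_max", "HI")


@dataclass(frozen=True)
class MetricSpec:
    """A dose-volume metric: Dx% / Dcc / VxGy / Dmin / Dmax / HI.

    ``argument`` is the x in Dx% (percent volume), the v in Dv cc (cm^3) or
    the d in Vd Gy (Gy); it is unused for D_min/D_max/HI.
    """

    kind: str
    argument: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _METRIC_KINDS:
            raise ProtocolError(f"unknown metric kind {self.kind!r}")
        if self.kind in ("D_percent", "D_cc", "V_gy") and self.argument <= 0:
            raise ProtocolError(f"{self.kind} requires a positive argument")
        if self.kind == "D_percent" and self.argument > 100:
            raise ProtocolError("D_percent argument must be <= 100")

    @property
    def result_units(self) -> str:
        return "%" if self.kind in ("V_gy", "HI") else "Gy"

    def label(self) -> str:
        if self.kind == "D_percent":
            return f"D{self.argument:g}%"
        if self.kind == "D_cc":
            return f"D{self.argument:g}cc"
        if self.kind == "V_gy":
            return f"V{self.argument:g}Gy"
        return {"D_min": "Dmin", "D_max": "Dmax", "HI": "HI"}[self.kind]

    @classmethod
    def parse(cls, text: str) -> "MetricSpec":
        """Parse labels like ``D2%``, ``D0.03cc``, ``V30Gy``, ``Dmin``, ``HI``."""
        s = text.strip().replace(" ", "")
        low = s.lower()
        if low == "hi":
            return cls("HI")
        if low == "dmin":
            return cls("D_min")
        if low == "dmax":
            return cls("D_max")
        m = re.fullmatch(r"[Dd]([0-9.]+)%", s)
        if m:
            return cls("D_percent", float(m.group(1)))
        m = re.fullmatch(r"[Dd]([0-9.]+)(?:cc|cm3)", s, re.IGNORECASE)
        if m:
            return cls("D_cc", float(m.group(1)))
        m = re.fullmatch(r"[Vv]([0-9.]+)(?:Gy)?", s)
        if m:
            return cls("V_gy", float(m.group(1)))
        raise ProtocolError(f"cannot parse metric specification {text!r}")


@dataclass(frozen=True)
class ClinicalGoal:
    """One protocol dose goal, e.g. PTV_3000 D2% <= 37.5 Gy."""

    structure_id: str
    metric: MetricSpec
    comparator: str  # "le" | "ge"
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in ("le", "ge"):
            raise ProtocolError(f"comparator must be 'le' or 'ge', got {self.comparator!r}")
        if not math.isfinite(self.threshold):
            raise ProtocolError("goal threshold must be finite")

    def satisfied_by(self, value: float) -> bool:
        return value <= self.threshold if self.comparator == "le" else value >= self.threshold

    def label(self) -> str:
        op = "<=" if self.comparator == "le" else ">="
        return f"{self.structure_id} {self.metric.label()} {op} {self.threshold:g} {self.metric.result_units}"


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldTemplate:
    """Templated treatment field in IEC 61217 angles."""

    field_id: str
    technique: str  # "arc" | "static"
    gantry_start: float
    gantry_stop: float
    rotation_direction: str  # "CW" | "CC"
    collimator_angle: float
    couch_angle: float = 0.0
    energy_label: str = "6X"

    def __post_init__(self) -> None:
        if self.technique not in ("arc", "static"):
            raise ProtocolError(f"technique must be 'arc' or 'static', got {self.technique!r}")
        if self.rotation_direction not in ("CW", "CC"):
            raise ProtocolError(f"rotation must be 'CW' or 'CC', got {self.rotation_direction!r}")
        if not (0 <= self.gantry_start < 360):
            raise ProtocolError(f"gantry_start must lie in [0, 360), got {self.gantry_start}")
        if self.technique == "arc" and self.gantry_start == self.gantry_stop:
            raise ProtocolError(f"arc field {self.field_id!r} has zero span")


@dataclass
class Prescription:
    total_dose_gy: float
    fractions: int
    dose_per_fraction_gy: float
    target_id: str

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ProtocolError("prescription target id must be non-empty")
        expected = self.fractions * self.dose_per_fraction_gy
        if abs(expected - self.total_dose_gy) > _DOSE_TOL:
            raise ProtocolError(
                f"prescription arithmetic inconsistent: {self.fractions} x "
                f"{self.dose_per_fraction_gy} Gy != {self.total_dose_gy} Gy"
            )


@dataclass
class ClinicalProtocol:
    protocol_id: str
    prescription: Prescription
    field_templates: list[FieldTemplate]
    default_machine_id: str
    clinical_goals: list[ClinicalGoal] = field(default_factory=list)
    expected_structures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.field_templates:
            raise ProtocolError(f"protocol {self.protocol_id!r} declares no fields")


def _req(elem: etree._Element, name: str) -> etree._Element:
    child = elem.find(name)
    if child is None:
        raise ProtocolError(f"protocol element <{elem.tag}> is missing <{name}>")
    return child


def _req_attr(elem: etree._Element, name: str) -> str:
    val = elem.get(name)
    if val is None:
        raise ProtocolError(f"element <{elem.tag}> is missing attribute {name!r}")
    return val


def parse_clinical_protocol(document: str | bytes, validate_schema: bool = True) -> ClinicalProtocol:
    """Parse (and optionally XSD-validate) a clinical-protocol XML document."""
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ProtocolError(f"protocol is not well-formed XML: {exc}") from exc
    if validate_schema:
        schema = etree.XMLSchema(etree.parse(str(packaged_data_path("clinical_protocol.xsd"))))
        if not schema.validate(root):
            raise ProtocolError(
                "protocol does not conform to schema: "
                + "; ".join(str(e.message) for e in schema.error_log)
            )
    if root.tag != "ClinicalProtocol":
        raise ProtocolError(f"root element must be <ClinicalProtocol>, got <{root.tag}>")

    rx_el = _req(root, "Prescription")
    rx = Prescription(
        total_dose_gy=float(_req_attr(rx_el, "totalDoseGy")),
        fractions=int(_req_attr(rx_el, "fractions")),
        dose_per_fraction_gy=float(_req_attr(rx_el, "dosePerFractionGy")),
        target_id=_req_attr(rx_el, "target"),
    )
    machine = _req_attr(_req(root, "Machine"), "id")
    fields_el = _req(root, "Fields")
    templates = [
        FieldTemplate(
            field_id=_req_attr(f, "id"),
            technique=_req_attr(f, "technique"),
            gantry_start=float(_req_attr(f, "gantryStart")),
            gantry_stop=float(_req_attr(f, "gantryStop")),
            rotation_direction=_req_attr(f, "rotation"),
            collimator_angle=float(_req_attr(f, "collimator")),
            couch_angle=float(f.get("couch", "0")),
            energy_label=f.get("energy", "6X"),
        )
        for f in fields_el.findall("Field")
    ]
    goals = []
    goals_el = root.find("Goals")
    if goals_el is not None:
        for g in goals_el.findall("Goal"):
            goals.append(
                ClinicalGoal(
                    structure_id=_req_attr(g, "structure"),
                    metric=MetricSpec.parse(_req_attr(g, "metric")),
                    comparator=_req_attr(g, "compare"),
                    threshold=float(_req_attr(g, "threshold")),
                )
            )
    expected = [
        _req_attr(s, "id") for s in root.findall("ExpectedStructures/Structure")
    ]
    return ClinicalProtocol(
        protocol_id=_req_attr(root, "id"),
        prescription=rx,
        field_templates=templates,
        default_machine_id=machine,
        clinical_goals=goals,
        expected_structures=expected,
    )


def serialize_clinical_protocol(protocol: ClinicalProtocol) -> str:
    """Inverse of :func:`parse_clinical_protocol` (round-trip safe)."""
    root = etree.Element("ClinicalProtocol", id=protocol.protocol_id)
    rx = protocol.prescription
    etree.SubElement(
        root,
        "Prescription",
        totalDoseGy=f"{rx.total_dose_gy:g}",
        fractions=str(rx.fractions),
        dosePerFractionGy=f"{rx.dose_per_fraction_gy:g}",
        target=rx.target_id,
    )
    etree.SubElement(root, "Machine", id=protocol.default_machine_id)
    fields = etree.SubElement(root, "Fields")
    for f in protocol.field_templates:
        etree.SubElement(
            fields,
            "Field",
            id=f.field_id,
            technique=f.technique,
            gantryStart=f"{f.gantry_start:g}",
            gantryStop=f"{f.gantry_stop:g}",
            rotation=f.rotation_direction,
            collimator=f"{f.collimator_angle:g}",
            couch=f"{f.couch_angle:g}",
            energy=f.energy_label,
        )
    goals = etree.SubElement(root, "Goals")
    for g in protocol.clinical_goals:
        etree.SubElement(
            goals,
            "Goal",
            structure=g.structure_id,
            metric=g.metric.label(),
            compare=g.comparator,
            threshold=f"{g.threshold:g}",
        )
    if protocol.expected_structures:
        exp = etree.SubElement(root, "ExpectedStructures")
        for sid in protocol.expected_structures:
            etree.SubElement(exp, "Structure", id=sid)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# automation config
# ---------------------------------------------------------------------------

_RULE_VERBS = ("union", "intersection", "subtraction", "margin", "ring", "crop_to")


@dataclass(frozen=True)
class DerivationStep:
    """One instruction in a derivation rule.

    Operands name existing structures, outputs of earlier rules, or results of
    earlier steps within the same rule via ``$k`` (0-based step index).
    """

    verb: str
    operands: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verb not in _RULE_VERBS:
            raise ProtocolError(
                f"unknown derivation verb {self.verb!r}; allowed: {', '.join(_RULE_VERBS)}"
            )
        if not self.operands:
            raise ProtocolError(f"derivation step {self.verb!r} has no operands")
        if self.verb == "margin":
            mm = self.params.get("mm")
            if mm is None or abs(float(mm)) > 50:
                raise ProtocolError("margin step requires |mm| <= 50")
        if self.verb == "ring":
            if "outer_mm" not in self.params:
                raise ProtocolError("ring step requires outer_mm")


@dataclass(frozen=True)
class DerivationRule:
    output_id: str
    steps: tuple[DerivationStep, ...]

    def __post_init__(self) -> None:
        if not self.output_id:
            raise ProtocolError("derivation rule output id must be non-empty")
        if not self.steps:
            raise ProtocolError(f"rule {self.output_id!r} has no steps")


@dataclass
class AutomationConfig:
    derivation_rules: list[DerivationRule] = field(default_factory=list)
    model_structure_map: list[tuple[str, str]] = field(default_factory=list)
    target_dose_map: list[tuple[str, float]] = field(default_factory=list)
    algorithm_overrides: dict[str, str] = field(default_factory=dict)
    # goal structures evaluated on the union of bilateral component masks,
    # e.g. {"OpticNerve": ["OpticNerve_L", "OpticNerve_R"]}
    bilateral_structures: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.derivation_rules:
            if rule.output_id in seen:
                raise ProtocolError(f"duplicate derivation output {rule.output_id!r}")
            seen.add(rule.output_id)
        for planning, model in self.model_structure_map:
            if not planning or not model:
                raise ProtocolError("model_structure_map entries must be non-empty")

    def target_dose(self, target_id: str) -> float | None:
        for tid, dose in self.target_dose_map:
            if tid == target_id:
                return dose
        return None


def parse_automation_config(document: str) -> AutomationConfig:
    """Parse the YAML automation configuration."""
    try:
        data = yaml.safe_load(document)
    except yaml.YAMLError as exc:
        raise ProtocolError(f"automation config is not valid YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ProtocolError("automation config must be a mapping")

    rules = []
    for entry in data.get("derivation_rules") or []:
        steps = []
        for raw in entry.get("steps", []):
            raw = dict(raw)
            verb = raw.pop("verb", None)
            ops = raw.pop("operands", None)
            if verb is None or ops is None:
                raise ProtocolError(
                    f"rule {entry.get('output')!r}: each step needs 'verb' and 'operands'"
                )
            steps.append(DerivationStep(verb=verb, operands=tuple(ops), params=raw))
        rules.append(DerivationRule(output_id=entry.get("output", ""), steps=tuple(steps)))

    model_map = [
        (str(e["planning"]), str(e["model"])) for e in data.get("model_structure_map") or []
    ]
    dose_map = [
        (str(e["target"]), float(e["dose_gy"])) for e in data.get("target_dose_map") or []
    ]
    overrides = {str(k): str(v) for k, v in (data.get("algorithm_overrides") or {}).items()}
    bilateral = {
        str(k): [str(x) for x in v]
        for k, v in (data.get("bilateral_structures") or {}).items()
    }
    return AutomationConfig(
        derivation_rules=rules,
        model_structure_map=model_map,
        target_dose_map=dose_map,
        algorithm_overrides=overrides,
        bilateral_structures=bilateral,
    )


# ---------------------------------------------------------------------------
# structure dictionary and matching
# ---------------------------------------------------------------------------

@dataclass
class StructureDictionary:
    """Canonical structure id -> synonym list, loaded from XML."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for canonical, synonyms in self.entries.items():
            for syn in synonyms:
                key = syn.casefold()
                if key in owner and owner[key] != canonical:
                    raise ProtocolError(
                        f"synonym {syn!r} maps to both {owner[key]!r} and {canonical!r}"
                    )
                owner[key] = canonical

    def synonyms_of(self, requested: str) -> list[str]:
        """Synonyms of the canonical id that ``requested`` names (either way)."""
        req = requested.casefold()
        for canonical, synonyms in self.entries.items():
            names = {canonical.casefold()} | {s.casefold() for s in synonyms}
            if req in names:
                return [canonical, *synonyms]
        return []


def parse_structure_dictionary(document: str | bytes) -> StructureDictionary:
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ProtocolError(f"structure dictionary is not well-formed XML: {exc}") from exc
    entries: dict[str, list[str]] = {}
    for s in root.findall("Structure"):
        canonical = _req_attr(s, "id")
        entries[canonical] = [syn.text.strip() for syn in s.findall("Synonym") if syn.text]
    return StructureDictionary(entries=entries)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of resolving a requested structure name against a structure set."""

    requested: str
    matched: str | None
    tier: str  # "exact" | "synonym" | "normalized" | "none"

    def __post_init__(self) -> None:
        if self.tier not in ("exact", "synonym", "normalized", "none"):
            raise ValueError(f"unknown match tier {self.tier!r}")
        if (self.tier == "none") != (self.matched is None):
            raise ValueError("tier 'none' iff matched id is absent")

    @property
    def flagged(self) -> bool:
        return self.tier == "none"


class AmbiguousMatchError(ValueError):
    """More than one available structure matched at the winning tier."""


def _normalize(name: str) -> str:
    return re.sub(r"[ _\-]", "", name).casefold()


def match_structure(
    requested: str,
    available: list[str],
    dictionary: StructureDictionary | None = None,
) -> MatchResult:
    """Resolve a template structure name against the available structure ids.

    Tier precedence: (1) case-insensitive exact match; (2) dictionary synonym
    of the requested name's canonical id; (3) normalized comparison (spaces,
    underscores and hyphens stripped, casefolded). The first tier with exactly
    one hit wins; two or more hits within a tier raise
    :class:`AmbiguousMatchError`; no hit in any tier yields a flagged result.
    """
    dictionary = dictionary or StructureDictionary()

    tiers: list[tuple[str, list[str]]] = []
    exact = [a for a in available if a.casefold() == requested.casefold()]
    tiers.append(("exact", exact))
    syn_names = {n.casefold() for n in dictionary.synonyms_of(requested)}
    synonym = [a for a in available if a.casefold() in syn_names]
    tiers.append(("synonym", synonym))
    normalized = [a for a in available if _normalize(a) == _normalize(requested)]
    tiers.append(("normalized", normalized))

    for tier, hits in tiers:
        # deduplicate identical ids while preserving order
        uniq = list(dict.fromkeys(hits))
        if len(uniq) == 1:
            return MatchResult(requested=requested, matched=uniq[0], tier=tier)
        if len(uniq) > 1:
            raise AmbiguousMatchError(
                f"{requested!r} matches multiple structures at tier {tier!r}: {uniq}"
            )
    return MatchResult(requested=requested, matched=None, tier="none")


@dataclass(frozen=True)
class ModelMatchRow:
    planning_id: str
    model_id: str
    match: MatchResult
    dose_level_gy: float | None = None


def resolve_model_matches(
    config: AutomationConfig,
    available: list[str],
    dictionary: StructureDictionary | None = None,
) -> list[ModelMatchRow]:
    """Resolve every KBP model-map entry; unresolved rows are flagged, not dropped."""
    rows = []
    target_ids = {tid for tid, _ in config.target_dose_map}
    for planning_id, model_id in config.model_structure_map:
        try:
            match = match_structure(planning_id, available, dictionary)
        except AmbiguousMatchError:
            match = MatchResult(requested=planning_id, matched=None, tier="none")
        dose = config.target_dose(planning_id) if planning_id in target_ids else None
        rows.append(
            ModelMatchRow(
                planning_id=planning_id, model_id=model_id, match=match, dose_level_gy=dose
            )
        )
    return rows
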