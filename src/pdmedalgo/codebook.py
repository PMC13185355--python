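"""Drug and diagnosis code semantics.

The algorithm never reasons about raw ATC/ICD-10 strings directly; every
rule is phrased in terms of semantic classes ("levodopa", "antipsychotic",
"restless leg syndrome", ...).  The :class:`Codebook` maps codes to those
classes and is fully user-overridable from a YAML config, because the
exact registry code lists behind a deployment differ between healthcare
systems.  The default shipped here is a documented best-effort
reconstruction from the public ATC/ICD-10 hierarchies (ATC group N04 split
into the six antiparkinsonian subclasses, common N05A antipsychotics); it
is not a transcription of any registry's internal list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import yaml

#: APM subclasses recognized by the rules.
APM_CLASSES = (
    "levodopa",
    "dopamine_agonist",
    "mao_inhibitor",
    "amantadine",
    "comt_inhibitor",
    "anticholinergic",
)

#: Diagnosis condition sets every rule may reference.
DX_CONDITIONS = (
    "pd",
    "hyperprolactinemia",
    "pituitary_adenoma",
    "pregnancy_or_birth",
    "hydrocephalus",
    "anoxic_brain_injury",
    "tbi",
    "coma",
    "psp",
    "msa",
    "cbd",
    "rls",
    "recurrent_falls",
    "lethargy",
    "general_deterioration",
    "constipation",
    "tremor",
    "tremor_nos",
    "depressive_episode",
    "tobacco_disorder",
    "heavy_smoker",
)


def _norm(code: str) -> str:
    """Normalize a code for dot-insensitive prefix matching."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class Codebook:
    """Maps ATC-5 drug codes and ICD-10 diagnosis codes to semantic classes.

    ICD-10 matching is dot-insensitive prefix matching: the set entry
    ``"K59"`` matches ``K59``, ``K59.0`` and ``K590``.  ATC codes are
    matched exactly after whitespace/case normalization.
    """

    apm_classes: Mapping[str, frozenset[str]]
    antipsychotics: frozenset[str]
    quetiapine_codes: frozenset[str]
    bromocriptine_codes: frozenset[str]
    pergolide_codes: frozenset[str]
    cabergoline_codes: frozenset[str]
    dx_sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cls_name, codes in self.apm_classes.items():
            if cls_name not in APM_CLASSES:
                raise ValueError(f"unknown APM class {cls_name!r}")
            for c in codes:
                if c in seen:
                    raise ValueError(
                        f"ATC code {c} in both {seen[c]!r} and {cls_name!r}"
                    )
                seen[c] = cls_name
        overlap = frozenset(seen) & self.antipsychotics
        if overlap:
            raise ValueError(f"codes in both APM and antipsychotic sets: {sorted(overlap)}")
        missing = [c for c in DX_CONDITIONS if not self.dx_sets.get(c)]
        if missing:
            raise ValueError(f"diagnosis conditions without codes: {missing}")

    # ---- drug side -------------------------------------------------
    def apm_class_of(self, atc_code: str) -> Optional[str]:
        code = _norm(atc_code)
        for cls_name, codes in self.apm_classes.items():
            if code in codes:
                return cls_name
        return None

    def is_antipsychotic(self, atc_code: str) -> bool:
        return _norm(atc_code) in self.antipsychotics

    def is_quetiapine(self, atc_code: str) -> bool:
        return _norm(atc_code) in self.quetiapine_codes

    # ---- diagnosis side --------------------------------------------
    def dx_matches(self, icd10_code: str, condition: str) -> bool:
        prefixes = self.dx_sets.get(condition)
        if prefixes is None:
            raise KeyError(f"unknown diagnosis condition {condition!r}")
        code = _norm(icd10_code)
        return any(code.startswith(p) for p in prefixes)

    def with_overrides(self, overrides: Mapping) -> "Codebook":
        """Return a copy with selected code sets replaced."""
        kwargs: dict = {}
        if "apm_classes" in overrides:
            merged = dict(self.apm_classes)
            for k, v in overrides["apm_classes"].items():
                merged[k] = frozenset(_norm(c) for c in v)
            kwargs["apm_classes"] = merged
        for key in ("antipsychotics", "quetiapine_codes", "bromocriptine_codes",
                    "pergolide_codes", "cabergoline_codes"):
            if key in overrides:
                kwargs[key] = frozenset(_norm(c) for c in overrides[key])
        if "dx_sets" in overrides:
            merged = dict(self.dx_sets)
            for k, v in overrides["dx_sets"].items():
                merged[k] = frozenset(_norm(c) for c in v)
            kwargs["dx_sets"] = merged
        return replace(self, **kwargs)


def _fs(codes: Iterable[str]) -> frozenset[str]:
    return frozenset(_norm(c) for c in codes)


def default_codebook() -> Codebook:
    """Default code lists (ATC N04 split into subclasses; common N05A)."""
    return Codebook(
        apm_classes={
            "levodopa": _fs(["N04BA01", "N04BA02", "N04BA03", "N04BA04", "N04BA05", "N04BA06"]),
            "dopamine_agonist": _fs([
                "N04BC01",  # bromocriptine
                "N04BC02",  # pergolide
                "N04BC04",  # ropinirole
                "N04BC05",  # pramipexole
                "N04BC06",  # cabergoline
                "N04BC07",  # apomorphine
                "N04BC08",  # piribedil
                "N04BC09",  # rotigotine
            ]),
            "mao_inhibitor": _fs(["N04BD01", "N04BD02", "N04BD03"]),
            "amantadine": _fs(["N04BB01"]),
            "comt_inhibitor": _fs(["N04BX01", "N04BX02", "N04BX04"]),
            "anticholinergic": _fs(["N04AA01", "N04AA02", "N04AA04", "N04AB02", "N04AC01"]),
        },
        antipsychotics=_fs([
            "N05AA01", "N05AA02", "N05AB02", "N05AB03", "N05AB04", "N05AB06",
            "N05AC02", "N05AD01", "N05AD05", "N05AE03", "N05AE04", "N05AF01",
            "N05AF03", "N05AF05", "N05AG02", "N05AH02", "N05AH03", "N05AH04",
            "N05AL01", "N05AL05", "N05AX08", "N05AX12", "N05AX13",
        ]),
        quetiapine_codes=_fs(["N05AH04"]),
        bromocriptine_codes=_fs(["N04BC01"]),
        pergolide_codes=_fs(["N04BC02"]),
        cabergoline_codes=_fs(["N04BC06"]),
        dx_sets={
            "pd": _fs(["G20"]),
            "hyperprolactinemia": _fs(["E221"]),
            "pituitary_adenoma": _fs(["D352", "E223"]),
            "pregnancy_or_birth": _fs(["O80", "O81", "O82", "O83", "O84", "Z37", "Z33"]),
            "hydrocephalus": _fs(["G91"]),
            "anoxic_brain_injury": _fs(["G931"]),
            "tbi": _fs(["S06"]),
            "coma": _fs(["R402"]),
            "psp": _fs(["G231"]),
            "msa": _fs(["G903", "G232"]),
            "cbd": _fs(["G239", "G3185"]),
            "rls": _fs(["G258"]),
            "recurrent_falls": _fs(["R296"]),
            "lethargy": _fs(["R53"]),
            "general_deterioration": _fs(["R54"]),
            "constipation": _fs(["K59"]),
            "tremor": _fs(["G250"]),
            "tremor_nos": _fs(["R521"]),
            "depressive_episode": _fs(["F32"]),
            "tobacco_disorder": _fs(["F17"]),
            "heavy_smoker": _fs(["Z720"]),
        },
    )


def load_codebook(path: str) -> Codebook:
    """Load a codebook from a YAML file of overrides on the default."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return default_codebook().with_overrides(raw.get("codebook", raw))
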