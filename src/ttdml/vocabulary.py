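"""Channel vocabulary: the fixed, ordered sets of clinical variables.

The model input dimension is tied to the *order* of the vocabulary, so the
order is part of the on-disk contract and is persisted with every cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Value kinds. ``continuous`` channels are z-scored during preprocessing,
#: ``ordinal`` channels are numeric-as-recorded (also z-scored), ``binary``
#: channels are passed through untouched.
CONTINUOUS = "continuous"
ORDINAL = "ordinal"
BINARY = "binary"

#: Default longitudinal channels: vitals, ventilation, neurological
#: assessments, labs and vasoactive/endocrine medication doses (k = 25).
DEFAULT_LONGITUDINAL: tuple[tuple[str, str], ...] = (
    ("bnp", CONTINUOUS),
    ("carboxyhemoglobin", CONTINUOUS),
    ("corneal_reflex", BINARY),
    ("fio2", CONTINUOUS),
    ("gag_reflex", BINARY),
    ("gcs", ORDINAL),
    ("hemoglobin", CONTINUOUS),
    ("lactate", CONTINUOUS),
    ("map", CONTINUOUS),
    ("methemoglobin", CONTINUOUS),
    ("o2_hemoglobin", CONTINUOUS),
    ("pco2", CONTINUOUS),
    ("peep", CONTINUOUS),
    ("ph", CONTINUOUS),
    ("po2", CONTINUOUS),
    ("pulse", CONTINUOUS),
    ("respirations", CONTINUOUS),
    ("spo2", CONTINUOUS),
    ("troponin_i", CONTINUOUS),
    ("troponin_t", CONTINUOUS),
    ("dopamine", CONTINUOUS),
    ("epinephrine", CONTINUOUS),
    ("levothyroxine", CONTINUOUS),
    ("lidocaine", CONTINUOUS),
    ("norepinephrine", CONTINUOUS),
)

#: Default static variables (l = 5). Sex and dialysis are {0,1}-encoded;
#: the mapping is persisted in the vocabulary file.
DEFAULT_STATIC: tuple[tuple[str, str], ...] = (
    ("age", CONTINUOUS),
    ("bmi", CONTINUOUS),
    ("dialysis", BINARY),
    ("sex", BINARY),
    ("weight", CONTINUOUS),
)

DEFAULT_ENCODINGS: dict[str, dict[str, int]] = {
    "sex": {"female": 0, "male": 1},
    "dialysis": {"no": 0, "yes": 1},
}


@dataclass(frozen=True)
class ChannelVocabulary:
    """Ordered longitudinal and static variable names with value kinds."""

    longitudinal_names: tuple[str, ...]
    static_names: tuple[str, ...]
    kinds: dict[str, str] = field(default_factory=dict)
    encodings: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.longitudinal_names) + list(self.static_names)
        if len(set(names)) != len(names):
            raise ValueError("vocabulary names must be unique")
        for name in names:
            self.kinds.setdefault(name, CONTINUOUS)

    @property
    def n_longitudinal(self) -> int:
        return len(self.longitudinal_names)

    @property
    def n_static(self) -> int:
        return len(self.static_names)

    def kind(self, name: str) -> str:
        return self.kinds[name]

    def longitudinal_index(self, name: str) -> int:
        return self.longitudinal_names.index(name)

    def static_index(self, name: str) -> int:
        return self.static_names.index(name)

    def is_binary(self, name: str) -> bool:
        return self.kinds[name] == BINARY

    def to_yaml(self, path) -> None:
        payload = {
            "longitudinal": [
                {"name": n, "kind": self.kinds[n]} for n in self.longitudinal_names
            ],
            "static": [
                {"name": n, "kind": self.kinds[n]} for n in self.static_names
            ],
            "encodings": self.encodings,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "ChannelVocabulary":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        longitudinal = tuple(e["name"] for e in payload["longitudinal"])
        static = tuple(e["name"] for e in payload["static"])
        kinds = {e["name"]: e["kind"] for e in payload["longitudinal"] + payload["static"]}
        return cls(longitudinal, static, kinds, payload.get("encodings", {}))


def default_vocabulary() -> ChannelVocabulary:
    """The 25-longitudinal / 5-static clinical vocabulary."""
    kinds = {n: k for n, k in DEFAULT_LONGITUDINAL}
    kinds.update({n: k for n, k in DEFAULT_STATIC})
    return ChannelVocabulary(
        longitudinal_names=tuple(n for n, _ in DEFAULT_LONGITUDINAL),
        static_names=tuple(n for n, _ in DEFAULT_STATIC),
        kinds=kinds,
        encodings={k: dict(v) for k, v in DEFAULT_ENCODINGS.items()},
    )
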