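"""Loaders for the lexicons and rule tables bundled with the package.

Everything here is a plain text/CSV/YAML file under ``mdslisten/data`` so
that every rule driving classification and de-identification is auditable
and editable without touching code.
"""

from __future__ import annotations

import csv
from importlib import resources as _ir
from pathlib import Path

import yaml

_DATA = _ir.files("mdslisten") / "data"


def data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def _read_lines(name: str) -> list[str]:
    text = (_DATA / name).read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def load_brand_map_table() -> dict[str, str]:
    """Brand name -> INN mapping (CSV with header ``brand,inn``)."""
    with data_path("brand_map.csv").open(encoding="utf-8") as fh:
        return {row["brand"]: row["inn"] for row in csv.DictReader(fh)}


def load_given_names() -> list[str]:
    return _read_lines("given_names.txt")


def load_surnames() -> list[str]:
    return _read_lines("surnames.txt")


def load_manufacturers() -> list[str]:
    return _read_lines("manufacturers.txt")


def load_institutions() -> list[str]:
    return _read_lines("institutions.txt")


def load_investigational_drugs() -> list[str]:
    return _read_lines("investigational_drugs.txt")


def load_role_phrases() -> dict:
    return yaml.safe_load(data_path("role_phrases.yaml").read_text(encoding="utf-8"))


def load_risk_markers() -> dict:
    return yaml.safe_load(data_path("risk_markers.yaml").read_text(encoding="utf-8"))


def load_theme_hierarchy_config() -> dict:
    return yaml.safe_load(data_path("theme_hierarchy.yaml").read_text(encoding="utf-8"))


def load_emotion_cues() -> dict:
    return yaml.safe_load(data_path("emotion_cues.yaml").read_text(encoding="utf-8"))


def wordlist_path() -> Path:
    return data_path("wordlist.txt")
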