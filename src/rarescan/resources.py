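"""Access to the data files bundled with the package."""

from __future__ import annotations

from importlib import resources as _res

from .dictionary import RareDiseaseEntry, load_dictionary

#: ORPHA codes of the 19-disease reporting panel bundled as the default
#: classification target set.
PANEL_CODES = (
    "97120", "1516", "93108", "355", "303", "90291", "805", "716", "586",
    "442", "666", "791", "72", "116", "558", "739", "881", "904", "3303",
)


def data_path(name: str):
    return _res.files("rarescan").joinpath(f"data/{name}")


def data_text(name: str) -> str:
    return data_path(name).read_text("utf-8")


def bundled_dictionary() -> list[RareDiseaseEntry]:
    """The demonstration dictionary shipped with the package."""
    with _res.as_file(data_path("panel_dictionary.tsv")) as path:
        return load_dictionary(path, format="tsv")


def bundled_panel() -> dict[str, str]:
    """Default panel: ORPHA code -> display name, from the bundled dictionary."""
    names = {e.orpha_code: e.preferred_name for e in bundled_dictionary()}
    return {code: names[code] for code in PANEL_CODES}
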