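"""Assembly of per-stage outputs into one structured JSON-able report."""

from __future__ import annotations

import datetime
import platform
import sys
from dataclasses import asdict, is_dataclass
from typing import Any, Mapping

import numpy as np

#: section names a report may contain, one per analysis stage
KNOWN_SECTIONS = ("nuclei", "calcium", "achr", "sarcomere", "qpcr", "stats")


class ReportError(ValueError):
    pass


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def build_report(
    sections: Mapping[str, Any],
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> dict:
    """Combine stage outputs into one report dictionary.

    ``sections`` maps a stage name (see ``KNOWN_SECTIONS``) to that
    stage's output (dataclasses, dicts, arrays — anything JSON-able
    after conversion).  Raises on empty input, unknown section names,
    or conflicting ``pixel_size`` entries across sections.
    """
    if not sections:
        raise ReportError("report needs at least one stage output")
    unknown = [k for k in sections if k not in KNOWN_SECTIONS]
    if unknown:
        raise ReportError(f"unknown sections: {unknown} (expected {KNOWN_SECTIONS})")

    pixel_sizes = {}
    for name, payload in sections.items():
        p = payload.get("pixel_size") if isinstance(payload, Mapping) else None
        if p is not None:
            pixel_sizes[name] = float(p)
    if len(set(pixel_sizes.values())) > 1:
        raise ReportError(f"conflicting pixel sizes across inputs: {pixel_sizes}")

    from . import __version__

    return {
        "sections": {k: _jsonable(v) for k, v in sections.items()},
        "provenance": {
            "package": "myotubekit",
            "version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
            "seed": seed,
            "config": _jsonable(config) if config else None,
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    }


def validate_report(report: Mapping[str, Any]) -> None:
    """Schema check: raises ``ReportError`` on malformed reports."""
    for key in ("sections", "provenance"):
        if key not in report:
            raise ReportError(f"missing top-level key {key!r}")
    if not report["sections"]:
        raise ReportError("report has no sections")
    unknown = [k for k in report["sections"] if k not in KNOWN_SECTIONS]
    if unknown:
        raise ReportError(f"unknown sections: {unknown}")
    prov = report["provenance"]
    for key in ("package", "version", "created"):
        if key not in prov:
            raise ReportError(f"missing provenance key {key!r}")
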