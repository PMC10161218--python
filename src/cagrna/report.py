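"""Markdown/JSON report layer over the analysis results directory.

Collects the JSON records written by the fitting commands and drivers and
renders one human-readable Markdown summary.  No plotting: the report is a
table layer, figures belong to the analysis drivers.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import thermo
from .thermo import MeltingParameters

__all__ = ["melting_record", "render_report"]


def melting_record(fit, n_jumps_used: int | None = None) -> dict:
    """JSON-ready summary of one melting fit (tjump.MeltingFitResult)."""
    from .groupstats import gaussian_error_prop

    p = fit.params
    dg37 = thermo.delta_g_37(p)
    return {
        "T_m": p.tm, "sigma_T_m": p.sigma_tm,
        "g1": p.g1, "sigma_g1": p.sigma_g1,
        "dG37": dg37, "sigma_dG37": gaussian_error_prop(p),
        "K37": thermo.equilibrium_constant(dg37, thermo.T_REF),
        "f_folded_37": thermo.folded_fraction(dg37, thermo.T_REF),
        "n_jumps_used": n_jumps_used if n_jumps_used is not None else fit.n_points,
        "flagged": fit.flagged, "message": fit.message,
    }


def render_report(results_dir, out_path) -> str:
    """Render every ``*.json`` record under ``results_dir`` into Markdown."""
    results_dir = Path(results_dir)
    lines = ["# Analysis report", ""]
    for path in sorted(results_dir.glob("*.json")):
        lines.append(f"## {path.stem}")
        lines.append("")
        record = json.loads(path.read_text())
        lines.append("```json")
        lines.append(json.dumps(record, indent=2))
        lines.append("```")
        lines.append("")
    text = "\n".join(lines)
    Path(out_path).write_text(text)
    return text
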