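"""Serialization of solutions: plain text, LaTeX, and JSON expression trees.

JSON expression trees are nested prefix lists, e.g. ``k2/k4`` becomes
``["div", "k2", "k4"]``; they round-trip through :func:`decode_expr`.
"""

from __future__ import annotations

import json
from typing import Any, Sequence

import sympy as sp

from .assembly import ConservationLaw, MergedSolution

__all__ = ["encode_expr", "decode_expr", "serialize_solution"]

FORMATS = ("text", "latex", "json")


def encode_expr(e: sp.Expr) -> Any:
    """Encode a sympy expression as a nested prefix list."""
    e = sp.sympify(e)
    if e.is_Symbol:
        return str(e)
    if e.is_Integer:
        return int(e)
    if e.is_Rational:
        return ["div", int(e.p), int(e.q)]
    if e.is_Add:
        return ["add", *[encode_expr(a) for a in e.args]]
    if e.is_Mul:
        num, den = sp.fraction(sp.together(e))
        if den != 1:
            return ["div", encode_expr(num), encode_expr(den)]
        return ["mul", *[encode_expr(a) for a in e.args]]
    if e.is_Pow:
        base, exp = e.args
        if exp == sp.Rational(1, 2):
            return ["sqrt", encode_expr(base)]
        if exp.is_negative:
            return ["div", 1, encode_expr(base ** -exp)]
        return ["pow", encode_expr(base), encode_expr(exp)]
    if isinstance(e, sp.Float):
        return float(e)
    raise ValueError(f"cannot encode expression node {type(e).__name__}: {e}")


def decode_expr(node: Any) -> sp.Expr:
    """Inverse of :func:`encode_expr`."""
    if isinstance(node, str):
        return sp.Symbol(node, positive=True)
    if isinstance(node, (int, float)):
        return sp.nsimplify(node)
    op, *args = node
    parts = [decode_expr(a) for a in args]
    if op == "add":
        return sp.Add(*parts)
    if op == "mul":
        return sp.Mul(*parts)
    if op == "div":
        return parts[0] / parts[1]
    if op == "pow":
        return parts[0] ** parts[1]
    if op == "sqrt":
        return sp.sqrt(parts[0])
    raise ValueError(f"unknown operator {op!r}")


def serialize_solution(
    merged: MergedSolution,
    fmt: str = "text",
    laws: Sequence[ConservationLaw] = (),
) -> str:
    """Render a merged solution as text, standalone LaTeX, or JSON."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if fmt == "json":
        payload = {
            "steady_state": {s: encode_expr(e) for s, e in merged.expressions.items()},
            "free_parameters": list(merged.remaining_free),
            "substitutions": [[n, encode_expr(e)] for n, e in merged.substitutions],
            "conservation_laws": [str(l) for l in laws],
            "residual_equations": [encode_expr(e) for e in merged.residual_equations],
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    if fmt == "latex":
        lines = [
            r"\documentclass{article}",
            r"\usepackage{amsmath}",
            r"\begin{document}",
            r"\section*{Steady state}",
            r"\begin{align*}",
        ]
        for s, e in merged.expressions.items():
            lines.append(rf"{sp.latex(sp.Symbol(s.lower()))} &= {sp.latex(e)} \\")
        lines.append(r"\end{align*}")
        if merged.remaining_free:
            names = ", ".join(sp.latex(sp.Symbol(_pretty(n))) for n in merged.remaining_free)
            lines.append(rf"Free parameters: ${names}$.")
        else:
            lines.append("Free parameters: none.")
        if laws:
            lines.append(r"\section*{Conservation laws}")
            lines.append(r"\begin{align*}")
            for law in laws:
                lines.append(
                    rf"{sp.latex(law.lhs())} &= {sp.latex(law.conserved_symbol())} \\"
                )
            lines.append(r"\end{align*}")
        lines.append(r"\end{document}")
        return "\n".join(lines)
    # text
    lines = ["steady state:"]
    for s, e in merged.expressions.items():
        lines.append(f"  {s.lower()} = {e}")
    if merged.remaining_free:
        lines.append("free parameters: " + ", ".join(merged.remaining_free))
    else:
        lines.append("free parameters: none")
    for law in laws:
        lines.append(f"conservation law: {law}")
    for eq in merged.residual_equations:
        lines.append(f"unsolved merge equation: {eq} = 0")
    return "\n".join(lines) + "\n"


def _pretty(name: str) -> str:
    for greek in ("sigma", "tau"):
        if name.startswith(greek):
            return f"\\{greek}_{{{name[len(greek):]}}}"
    return name
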