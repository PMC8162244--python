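"""Model-formula parsing for random-intercept mixed models.

Supports a Wilkinson-style dialect: fixed effects combined with ``+``,
``*`` (crossing) and ``:`` (interaction), plus random intercepts written
``(1|group)``.  Random slopes, nesting sugar (``a/b``) and in-formula
transformations (``log(x)``, ``poly(x, 2)``) are deliberately rejected:
transformed columns must be precomputed in the data table so that term
labels match data columns exactly.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "ModelSpec",
    "FormulaError",
    "UnsupportedFeatureError",
    "parse_formula",
    "canonicalize_term",
]

#: family -> admissible links; the first entry is the canonical default.
SUPPORTED_FAMILIES = {
    "gaussian": ("identity",),
    "poisson": ("log", "sqrt"),
    "binomial": ("logit", "probit"),
}


class FormulaError(ValueError):
    """Raised when a formula cannot be parsed."""


class UnsupportedFeatureError(FormulaError):
    """Raised for syntax that is recognized but not supported (e.g. random slopes)."""


_NAME_RE = re.compile(r"^[A-Za-z_.][A-Za-z0-9_.]*$")
_RANDOM_RE = re.compile(r"^\(\s*(?P<lhs>[^|]+)\|\s*(?P<group>[^|]+)\)$")
_CBIND_RE = re.compile(r"^cbind\(\s*([A-Za-z_.][\w.]*)\s*,\s*([A-Za-z_.][\w.]*)\s*\)$")


@dataclass
class ModelSpec:
    """Declaration of a mixed model: response, fixed terms, random intercepts.

    ``response`` is a column name, or a ``(successes, failures)`` column pair
    for binomial proportion data.  ``fixed_terms`` are term labels (main
    effects and ``:`` interactions) in formula order; the intercept is
    implicit.  ``random_groups`` are grouping columns, each contributing one
    random intercept.
    """

    response: str | tuple[str, str]
    fixed_terms: list[str]
    random_groups: list[str]
    family: str = "gaussian"
    link: str | None = None

    def __post_init__(self) -> None:
        if self.family not in SUPPORTED_FAMILIES:
            raise ValueError(
                f"unsupported family {self.family!r}; "
                f"supported: {sorted(SUPPORTED_FAMILIES)}"
            )
        if self.link is None:
            self.link = SUPPORTED_FAMILIES[self.family][0]
        if self.link not in SUPPORTED_FAMILIES[self.family]:
            raise ValueError(
                f"unsupported family/link combination {self.family}+{self.link}; "
                f"links for {self.family}: {SUPPORTED_FAMILIES[self.family]}"
            )
        if not self.random_groups:
            raise ValueError(
                "at least one random intercept (1|group) is required: "
                "this is a mixed-model tool"
            )

    @property
    def response_columns(self) -> tuple[str, ...]:
        if isinstance(self.response, tuple):
            return self.response
        return (self.response,)

    def referenced_columns(self) -> list[str]:
        """All data columns the spec refers to (response, predictors, groups)."""
        cols: list[str] = list(self.response_columns)
        for term in self.fixed_terms:
            for part in term.split(":"):
                if part not in cols:
                    cols.append(part)
        for g in self.random_groups:
            if g not in cols:
                cols.append(g)
        return cols

    def validate_against(self, data) -> None:
        missing = [c for c in self.referenced_columns() if c not in data.columns]
        if missing:
            raise KeyError(f"columns referenced by the model are absent from the data: {missing}")


def canonicalize_term(term: str, column_order: list[str] | None = None) -> str:
    """Normalize whitespace in a term label and order interaction components.

    Components of an interaction are sorted by position in ``column_order``
    (the data's column order) so that ``a:b`` and ``b:a`` refer to the same
    term.  Unknown components keep their relative order after known ones.
    """
    parts = [p.strip() for p in term.split(":")]
    if column_order is not None and len(parts) > 1:
        order = {c: i for i, c in enumerate(column_order)}
        parts.sort(key=lambda p: (order.get(p, len(order)), p))
    return ":".join(parts)


def _check_name(tok: str) -> str:
    tok = tok.strip()
    if "(" in tok or ")" in tok:
        raise UnsupportedFeatureError(
            f"in-formula transformations are not supported (offending token: {tok!r}); "
            "precompute the transformed column in the data table"
        )
    if "/" in tok:
        raise UnsupportedFeatureError(
            f"nesting syntax is not supported (offending token: {tok!r})"
        )
    if not _NAME_RE.match(tok):
        raise FormulaError(f"cannot parse term (offending token: {tok!r})")
    return tok


def _split_top_level(text: str, sep: str) -> list[str]:
    """Split on ``sep`` outside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _expand_fixed(tok: str) -> list[str]:
    """Expand a single fixed-effect token into term labels (handles ``*``)."""
    if "*" in tok:
        factors = [_check_name(f) for f in tok.split("*")]
        terms = []
        for k in range(1, len(factors) + 1):
            for combo in itertools.combinations(factors, k):
                terms.append(":".join(combo))
        return terms
    if ":" in tok:
        return [":".join(_check_name(p) for p in tok.split(":"))]
    return [_check_name(tok)]


def parse_formula(formula_text: str) -> ModelSpec:
    """Parse a formula like ``"y ~ Rank * Time + (1|MaleID)"`` into a ModelSpec.

    ``a*b`` expands to ``a + b + a:b`` (term order preserved); random
    intercepts ``(1|g)`` populate ``random_groups``.  Family and link are not
    part of the formula; they are set on the returned spec by the caller.
    """
    sides = formula_text.split("~")
    if len(sides) != 2:
        raise FormulaError(
            f"formula must contain exactly one '~' (got {formula_text!r})"
        )
    lhs, rhs = sides[0].strip(), sides[1].strip()
    if not lhs:
        raise FormulaError("missing response on the left of '~'")

    m = _CBIND_RE.match(lhs)
    response: str | tuple[str, str]
    if m:
        response = (m.group(1), m.group(2))
    else:
        response = _check_name(lhs)

    fixed_terms: list[str] = []
    random_groups: list[str] = []
    for raw in _split_top_level(rhs, "+"):
        tok = raw.strip()
        if not tok:
            raise FormulaError("empty term between '+' signs")
        if tok == "0" or tok == "-1":
            raise UnsupportedFeatureError("intercept suppression is not supported")
        rm = _RANDOM_RE.match(tok)
        if rm:
            lhs_r = rm.group("lhs").strip()
            group = rm.group("group").strip()
            if lhs_r != "1":
                raise UnsupportedFeatureError(
                    f"random slopes are not supported (offending token: {tok!r}); "
                    "only random intercepts (1|group) are allowed"
                )
            random_groups.append(_check_name(group))
            continue
        if tok.startswith("("):
            raise FormulaError(f"cannot parse term (offending token: {tok!r})")
        if tok == "1":
            continue  # explicit intercept; always present anyway
        for term in _expand_fixed(tok):
            if term not in fixed_terms:
                fixed_terms.append(term)

    if not random_groups:
        raise FormulaError(
            "no random-intercept term found; add at least one (1|group)"
        )
    return ModelSpec(response=response, fixed_terms=fixed_terms, random_groups=random_groups)
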