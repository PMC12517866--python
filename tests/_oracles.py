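"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — pure-Python loops over plain dicts,
exact rational / high-precision arithmetic — and shares no code path with
the package implementation it checks (the only import from the package is
the drug-name normalizer's *contract*, re-implemented below).
"""

from __future__ import annotations

import math
import re
from fractions import Fraction


# ---------------------------------------------------------------------------
# ASCII parsing (naive line splitter, no pandas)
# ---------------------------------------------------------------------------

def read_ascii(path) -> list[dict]:
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if not lines:
        return []
    header = [h.strip().lower() for h in lines[0].split("$")]
    return [dict(zip(header, ln.split("$"))) for ln in lines[1:]]


def _int(s):
    try:
        return int(float(s))
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Deduplication: group-wise argmax of (padded fda_dt, primaryid)
# ---------------------------------------------------------------------------

def _fda_key(s: str) -> int:
    s = (s or "").strip()
    if not s.isdigit():
        return 0
    if len(s) == 4:
        s += "0101"
    elif len(s) == 6:
        s += "01"
    return int(s) if len(s) == 8 else 0


def dedup_oracle(demo_rows: list[dict]) -> set[int]:
    """Surviving primaryids: per caseid keep max (fda key, primaryid)."""
    best: dict[int, tuple[int, int]] = {}
    for row in demo_rows:
        cid, pid = _int(row["caseid"]), _int(row["primaryid"])
        key = (_fda_key(row.get("fda_dt", "")), pid)
        if cid not in best or key > best[cid]:
            best[cid] = key
    return {pid for _, pid in best.values()}


# ---------------------------------------------------------------------------
# Labeling oracles (linear / nested-loop scans)
# ---------------------------------------------------------------------------

_ORACLE_DOSE = re.compile(
    r"^(?:\d+(?:\.\d+)?\s*(?:MG|MCG|G|ML|IU|UG)?|MG|TABLETS?|TABS?|CAPSULES?|"
    r"CAPS?|INJECTION|SOLUTION|ORAL|FILM|COATED)$")


def normalize_name(name: str) -> str:
    tokens = name.upper().split()
    while tokens and _ORACLE_DOSE.match(tokens[-1]):
        tokens.pop()
    return " ".join(tokens)


def exposure_oracle(drug_rows: list[dict], survivors: set[int],
                    name_to_atc: dict, atc_code: str) -> set[int]:
    out = set()
    for row in drug_rows:
        pid = _int(row["primaryid"])
        if (pid in survivors and row["role_cod"].strip().upper() == "PS"
                and name_to_atc.get(normalize_name(row["drugname"])) == atc_code):
            out.add(pid)
    return out


def case_oracle(reac_rows: list[dict], survivors: set[int],
                pt_to_soc: dict, target_soc: int) -> set[int]:
    out = set()
    for row in reac_rows:
        pid = _int(row["primaryid"])
        if pid in survivors and pt_to_soc.get(_int(row["pt_code"])) == target_soc:
            out.add(pid)
    return out


def table_oracle(universe: set[int], exposed: set[int],
                 cases: set[int]) -> tuple[int, int, int, int]:
    a = b = c = d = 0
    for pid in universe:
        if pid in exposed:
            a, b = (a + 1, b) if pid in cases else (a, b + 1)
        else:
            c, d = (c + 1, d) if pid in cases else (c, d + 1)
    return a, b, c, d


def pt_count_oracle(reac_rows: list[dict], exposed_cases: set[int],
                    pt_to_soc: dict, target_soc: int,
                    pt_names: dict) -> dict[str, int]:
    seen: set[tuple[int, int]] = set()
    counts: dict[str, int] = {}
    for row in reac_rows:
        pid, pt = _int(row["primaryid"]), _int(row["pt_code"])
        if (pid in exposed_cases and pt_to_soc.get(pt) == target_soc
                and (pid, pt) not in seen):
            seen.add((pid, pt))
            name = pt_names.get(pt, str(pt))
            counts[name] = counts.get(name, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# High-precision formula oracles (sympy)
# ---------------------------------------------------------------------------

def ror_oracle(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """ROR and Woolf 95% CI recomputed with exact rationals + 50-digit logs."""
    import sympy as sp

    point = Fraction(a * d, b * c)
    ln_ror = sp.log(sp.Rational(a * d, b * c))
    se = sp.sqrt(sp.Rational(1, a) + sp.Rational(1, b)
                 + sp.Rational(1, c) + sp.Rational(1, d))
    z = sp.Rational(196, 100)
    low = sp.exp(ln_ror - z * se).evalf(50)
    high = sp.exp(ln_ror + z * se).evalf(50)
    return float(point), float(low), float(high)


def ic_oracle(a: int, b: int, c: int, d: int) -> float:
    """Observed/expected IC point value, in bits, at 50-digit precision."""
    import sympy as sp

    n = a + b + c + d
    val = sp.log(sp.Rational(a * n, (a + b) * (a + c)), 2).evalf(50)
    return float(val)


# ---------------------------------------------------------------------------
# Quantiles (closed-form type 7 on a sorted copy)
# ---------------------------------------------------------------------------

def quantile7(values, q: float) -> float:
    xs = sorted(float(v) for v in values)
    if not xs:
        raise ValueError("empty")
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
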