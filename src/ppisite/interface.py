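"""Surface- and interface-residue definitions from solvent accessibility.

A residue is a *surface* residue when its relative solvent accessibility in
the unbound monomer reaches a threshold (5% by default).  A surface residue
is an *interface* residue when it buries more than 1.0 A^2 of absolute
solvent accessibility upon complex formation, i.e. SA(monomer) - SA(complex)
strictly exceeds the threshold.  Interfaces are therefore always a subset of
the surface.

The RSA comparison direction is configurable because the exposure convention
is sometimes stated in the buried direction; the default here is the common
one: RSA >= threshold means exposed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

DEFAULT_SURFACE_RSA_THRESHOLD = 5.0  # percent
DEFAULT_DELTA_SA_THRESHOLD = 1.0  # A^2 lost upon binding


@dataclass(frozen=True)
class AccessibilityPair:
    """Solvent accessibility of one residue in monomer and complex forms."""

    sa_monomer: float  # absolute, A^2
    sa_complex: float  # absolute, A^2
    rsa_monomer: float  # relative, percent

    def __post_init__(self) -> None:
        if self.sa_monomer < 0 or self.sa_complex < 0:
            raise ValueError("absolute accessibilities must be >= 0")
        if not 0.0 <= self.rsa_monomer <= 100.0:
            raise ValueError(
                f"rsa_monomer must be in [0, 100], got {self.rsa_monomer}"
            )

    @property
    def delta_sa(self) -> float:
        """Accessibility lost upon binding (positive = buried)."""
        return self.sa_monomer - self.sa_complex


def is_surface(
    rsa: float,
    threshold: float = DEFAULT_SURFACE_RSA_THRESHOLD,
    exposed_above: bool = True,
) -> bool:
    """Classify a residue as surface from its monomer RSA.

    With ``exposed_above=True`` (default) a residue is surface when
    ``rsa >= threshold``; the flag flips the comparison for data prepared
    under the opposite convention.
    """
    if not 0.0 <= rsa <= 100.0:
        raise ValueError(f"rsa must be in [0, 100], got {rsa}")
    if exposed_above:
        return rsa >= threshold
    return rsa < threshold


def is_interface(
    pair: AccessibilityPair,
    delta_threshold: float = DEFAULT_DELTA_SA_THRESHOLD,
    surface_threshold: float = DEFAULT_SURFACE_RSA_THRESHOLD,
    exposed_above: bool = True,
) -> bool:
    """True iff the residue is surface and buries > ``delta_threshold`` A^2.

    The inequality on the buried area is strict.  A residue whose
    accessibility *grows* upon binding beyond numeric noise is suspicious
    (binding should only occlude surface) and triggers a warning, not an
    error.
    """
    if pair.delta_sa < -1e-6:
        logger.warning(
            "accessibility grew upon binding (monomer %.2f -> complex %.2f)",
            pair.sa_monomer,
            pair.sa_complex,
        )
    if not is_surface(pair.rsa_monomer, surface_threshold, exposed_above):
        return False
    return pair.delta_sa > delta_threshold


def label_accessibility_table(
    text: str,
    delta_threshold: float = DEFAULT_DELTA_SA_THRESHOLD,
    surface_threshold: float = DEFAULT_SURFACE_RSA_THRESHOLD,
    exposed_above: bool = True,
) -> str:
    """Flag surface/interface residues for a whitespace-separated table.

    Input rows are ``position rsa_monomer sa_monomer sa_complex``; the output
    is a TSV of ``position surface_flag interface_flag`` with 0/1 flags.
    """
    out = io.StringIO()
    out.write("position\tsurface\tinterface\n")
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens or tokens[0].startswith("#"):
            continue
        if len(tokens) != 4:
            raise ValueError(
                f"line {lineno}: expected 'position rsa_monomer sa_monomer "
                f"sa_complex', got {len(tokens)} fields"
            )
        pos = int(tokens[0])
        rsa_m, sa_m, sa_c = (float(t) for t in tokens[1:])
        pair = AccessibilityPair(sa_monomer=sa_m, sa_complex=sa_c, rsa_monomer=rsa_m)
        surf = is_surface(rsa_m, surface_threshold, exposed_above)
        iface = is_interface(pair, delta_threshold, surface_threshold, exposed_above)
        out.write(f"{pos}\t{int(surf)}\t{int(iface)}\n")
    return out.getvalue()
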