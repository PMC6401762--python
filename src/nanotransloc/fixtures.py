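"""Named parameter sets for the benchmark scenarios shipped with the package.

Each fixture reproduces one published experimental/theoretical setup:
solid-state pressure-voltage trapping (fig2), the alpha-Hemolysin
image-charge scenarios (fig6, fig7) and the IFTP waiting-time and
scaling benchmarks (fig9a/b, fig10a/b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import ATM_TO_PA
from .electrostatics import Electrolyte, PoreSystem
from .iftp import IFTPParams

__all__ = ["Fixture", "FIXTURES", "get_fixture", "list_fixtures"]


@dataclass(frozen=True)
class Fixture:
    """A named, citable parameter set for one of the two engines."""

    name: str
    engine: str  # "ehd" | "iftp"
    params: dict
    note: str
    sweep: dict = field(default_factory=dict)

    def build(self):
        """Instantiate the engine parameter object."""
        if self.engine == "ehd":
            p = dict(self.params)
            molar = p.pop("rho_molar")
            barrier = p.pop("barrier", "mf")
            el = Electrolyte.monovalent(molar)
            return PoreSystem(electrolyte=el, **p), barrier
        p = {k: v for k, v in self.params.items()}
        return IFTPParams(**p)


_ALPHA_HL = dict(
    # ss-DNA in an alpha-Hemolysin pore: tau = 0.29 e/A -> sigma_p =
    # tau/(2 pi a); the pore's alternating surface charge averages to zero.
    a=0.5, d=0.85, Lm=5.0, Lp=10.0,
    sigma_p=2.9 / (2.0 * 3.141592653589793 * 0.5),
    sigma_m=0.0,
    barrier="image",
)

FIXTURES: dict[str, Fixture] = {
    "fig2": Fixture(
        name="fig2",
        engine="ehd",
        params=dict(a=1.0, d=5.0, Lm=200.0, Lp=180.0, sigma_p=0.4,
                    sigma_m=0.13, delta_V=-100e-3, delta_P=2.0 * ATM_TO_PA,
                    rho_molar=1.6, barrier="mf"),
        sweep=dict(parameter="delta_P",
                   grid=[p * ATM_TO_PA for p in (0.5, 1, 2, 4, 8, 16)]),
        note=("Pressure-voltage trapping of a 615-bp ds-DNA (Lp = 180 nm) in "
              "a solid-state pore: dV = -100 mV, 1.6 M KCl, d = 5 nm, "
              "Lm = 200 nm, sigma_m = 0.13 e/nm2, sigma_p = 0.4 e/nm2. "
              "DNA radius a = 1 nm assumed (ds-DNA value; not printed for "
              "this setup). Base dP = 2 atm is a scan anchor."),
    ),
    "fig6": Fixture(
        name="fig6",
        engine="ehd",
        params=dict(delta_V=120e-3, delta_P=0.0, rho_molar=0.04, **_ALPHA_HL),
        sweep=dict(parameter="rho_molar", grid=[0.02, 0.04, 0.07, 0.1, 0.2, 0.5, 1.0]),
        note=("alpha-Hemolysin image-charge barrier: d = 8.5 A, a = 5 A, "
              "Lm = 5 nm, Lp = 10 nm, tau = 0.29 e/A, neutral membrane, "
              "dV = 120 mV; base salt 0.04 M (barrier-dominated point)."),
    ),
    "fig7": Fixture(
        name="fig7",
        engine="ehd",
        params=dict(delta_V=150e-3, delta_P=0.0, rho_molar=0.1, **_ALPHA_HL),
        sweep=dict(parameter="delta_V",
                   grid=[v * 1e-3 for v in (50, 100, 150, 200, 250, 300)]),
        note=("Capture-rate turnover with voltage in alpha-Hemolysin; same "
              "pore as fig6, base dV = 150 mV (trap-dominated point of the "
              "published potential inset), base salt 0.1 M."),
    ),
    "fig9a": Fixture(
        name="fig9a",
        engine="iftp",
        params=dict(N0=128, f=5.0, eta_p=3.5, A_nu=1.15, nu=0.588,
                    gamma_prime=0.69, mode="pore"),
        note="Pore-driven IFTP waiting-time benchmark: N0 = 128, f = 5, "
             "eta_p = 3.5, 3D self-avoiding chain.",
    ),
    "fig9b": Fixture(
        name="fig9b",
        engine="iftp",
        params=dict(N0=100, f=100.0, eta_p=3.0, A_nu=1.15, nu=0.588,
                    gamma_prime=0.69, mode="end"),
        note="End-pulled IFTP waiting-time benchmark: N0 = 100, f = 100, "
             "eta_p = 3.",
    ),
    "fig10a": Fixture(
        name="fig10a",
        engine="iftp",
        params=dict(N0=128, f=5.0, eta_p=1.0, A_nu=1.15, nu=0.588,
                    gamma_prime=0.69, mode="pore"),
        sweep=dict(parameter="eta_p", grid=[1.0, 5.0, 10.0],
                   N0=[128, 256, 512, 1024, 2048, 4096, 8192]),
        note="Pore-driven scaling sweep: f = 5, A_nu = 1.15, "
             "eta_p in {1, 5, 10}; rescaled exponent 1 + nu = 1.588.",
    ),
    "fig10b": Fixture(
        name="fig10b",
        engine="iftp",
        params=dict(N0=64, f=100.0, eta_p=1.5, A_nu=1.15, nu=0.588,
                    gamma_prime=0.69, mode="end"),
        sweep=dict(parameter="eta_p", grid=[1.5, 10.0, 20.0],
                   N0=[64, 128, 256, 512, 1024, 2048, 4096]),
        note="End-pulled scaling sweep: f = 100, eta_p in {1.5, 10, 20}; "
             "trans-side-rescaled exponent 2.",
    ),
}


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(FIXTURES)}") from None


def list_fixtures():
    """Tidy table of the packaged fixtures."""
    import pandas as pd

    rows = [{"name": f.name, "engine": f.engine, "note": f.note}
            for f in FIXTURES.values()]
    return pd.DataFrame(rows)
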