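"""Stimulus-dosing arithmetic for vesicle shape-change experiments.

A well of vesicle suspension is perturbed by adding concentrated buffer
stock (raising the osmolyte concentration by dC_V, the hyperosmotic
shock) and micelle stock (raising the lipid concentration by dC_A, the
membrane-growth stimulus).  The stock volumes realizing a requested
(dC_V, dC_A) follow conservation of moles:

    buffer:  v = dC_V * V0 / (C_stock - C0 - dC_V)
    micelle: v = dC_A * V0 / C_stock                (nominal)
             v = dC_A * V0 / (C_stock - C0 - dC_A)  (exact, self-diluted)

The buffer equation accounts for the added volume diluting the stock
itself (ignoring the co-added micelle volume); the nominal micelle
convention neglects self-dilution, matching bench bookkeeping.  Dilutions
and sequential stimuli track every named species by volume-weighted
mixing.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InfeasibleStockError

__all__ = [
    "SolutionState",
    "StockSpec",
    "StimulusSpec",
    "buffer_volume_for_shock",
    "micelle_volume_for_growth",
    "dilute",
    "apply_stimulus",
]

BUFFER = "Na-bicine"
LIPID = "oleate"


@dataclass
class SolutionState:
    """A well: volume in uL and concentrations (mM) of named species."""

    volume: float
    concentrations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"concentration of {name} must be >= 0")

    def conc(self, name: str) -> float:
        return float(self.concentrations.get(name, 0.0))


@dataclass
class StockSpec:
    """A stock solution: a single species at a concentration in mM."""

    name: str
    concentration: float

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("stock concentration must be > 0")


@dataclass
class StimulusSpec:
    """A simultaneous osmotic-shock / micelle-addition event.

    dcv: target Na-bicine increase (mM); dca: target oleate increase
    (mM); co_added: inert tracers spiked to the given final
    concentrations (mM).
    """

    dcv: float = 0.0
    dca: float = 0.0
    co_added: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dcv < 0 or self.dca < 0:
            raise ValueError("stimulus magnitudes must be >= 0")


def buffer_volume_for_shock(state: SolutionState, stock: StockSpec,
                            dcv: float) -> float:
    """Stock volume (uL) raising the buffer concentration by dcv mM.

    Mole balance including the added volume, ignoring the co-added
    micelle volume: v = dcv*V0/(C_stock - C0 - dcv).
    """
    if dcv == 0:
        return 0.0
    c0 = state.conc(BUFFER)
    denom = stock.concentration - c0 - dcv
    if denom <= 0:
        raise InfeasibleStockError(
            f"stock at {stock.concentration} mM cannot raise "
            f"{c0} mM by {dcv} mM")
    return dcv * state.volume / denom


def micelle_volume_for_growth(state: SolutionState, stock: StockSpec,
                              dca: float, mode: str = "nominal") -> float:
    """Micelle-stock volume (uL) raising the lipid concentration by dca.

    "nominal" neglects self-dilution (v = dca*V0/C_stock, the bench
    convention); "exact" applies the full mixing equation.
    """
    if dca == 0:
        return 0.0
    if mode == "nominal":
        if stock.concentration <= dca:
            raise InfeasibleStockError("stock too dilute for requested dca")
        return dca * state.volume / stock.concentration
    if mode == "exact":
        c0 = state.conc(LIPID)
        denom = stock.concentration - c0 - dca
        if denom <= 0:
            raise InfeasibleStockError("stock too dilute for requested dca")
        return dca * state.volume / denom
    raise ValueError(f"unknown mode {mode!r}")


def _mix(states):
    """Volume-weighted mixing of (volume, concentrations) pairs."""
    total = sum(v for v, _ in states)
    species = set()
    for _, conc in states:
        species.update(conc)
    mixed = {name: sum(v * conc.get(name, 0.0) for v, conc in states) / total
             for name in sorted(species)}
    return SolutionState(volume=total, concentrations=mixed)


def dilute(state: SolutionState, parts_sample: int, parts_diluent: int,
           diluent: dict | None = None) -> SolutionState:
    """Mix `parts_sample` of the state with `parts_diluent` of a diluent
    whose species map defaults to empty (species absent = 0)."""
    if parts_sample <= 0 or parts_diluent < 0:
        raise ValueError("parts must be positive (diluent may be 0)")
    if parts_diluent == 0:
        return replace(state)
    unit = state.volume / parts_sample
    return _mix([
        (state.volume, state.concentrations),
        (unit * parts_diluent, dict(diluent or {})),
    ])


def apply_stimulus(state: SolutionState, stim: StimulusSpec,
                   mode: str = "nominal",
                   buffer_stock: StockSpec | None = None,
                   micelle_stock: StockSpec | None = None) -> SolutionState:
    """Well composition after one shock + micelle-addition event.

    "nominal" mode adds dcv and dca to the running concentrations (the
    bench bookkeeping, which reproduces the reported sequential
    endpoints); "exact" mode computes stock volumes and applies full
    volume-weighted mixing.  Co-added tracers are spiked to their target
    final concentrations in both modes.
    """
    if mode == "nominal":
        conc = dict(state.concentrations)
        conc[BUFFER] = conc.get(BUFFER, 0.0) + stim.dcv
        conc[LIPID] = conc.get(LIPID, 0.0) + stim.dca
        for name, c in stim.co_added.items():
            conc[name] = c
        return SolutionState(volume=state.volume, concentrations=conc)
    if mode == "exact":
        buffer_stock = buffer_stock or StockSpec(BUFFER, 1000.0)
        micelle_stock = micelle_stock or StockSpec(LIPID, 100.0)
        vb = buffer_volume_for_shock(state, buffer_stock, stim.dcv)
        vm = micelle_volume_for_growth(state, micelle_stock, stim.dca,
                                       mode="exact")
        parts = [(state.volume, state.concentrations)]
        if vb > 0:
            parts.append((vb, {BUFFER: buffer_stock.concentration}))
        if vm > 0:
            parts.append((vm, {LIPID: micelle_stock.concentration}))
        out = _mix(parts)
        conc = dict(out.concentrations)
        for name, c in stim.co_added.items():
            conc[name] = c
        return SolutionState(volume=out.volume, concentrations=conc)
    raise ValueError(f"unknown mode {mode!r}")
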