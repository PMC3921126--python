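"""Assembled analysis reports: everything the toolkit can say about a network.

An :class:`AnalysisReport` bundles the canonical network, its constitutive
equation, shapes, type trace, local and global verdicts, optional oracle
results and any warnings (e.g. that a fixture is a text-level
reconstruction).  Both the structured (JSON) and human-readable renderings
carry identical verdicts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .constitutive import ConstitutiveEquation, coefficient_map, derive_constitutive
from .identifiability import (
    GlobalVerdict,
    LocalVerdict,
    global_identifiability,
    jacobian_rank_oracle,
    preimage_count_oracle,
)
from .networks import Network, network_to_dict
from .operators import GenericEvaluator
from .typecalc import TypeLabel, TypeTrace, tau

SCHEMA_VERSION = 1

__all__ = ["AnalysisReport", "analyze"]


@dataclass
class AnalysisReport:
    input_text: str
    network: Network
    equation: ConstitutiveEquation
    type_label: TypeLabel
    trace: TypeTrace
    local: LocalVerdict
    global_: GlobalVerdict
    coefficients: tuple  # (label, expression string) pairs
    oracle: Optional[dict] = None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "input": self.input_text,
            "canonical_expression": self.network.serialize(),
            "network": network_to_dict(self.network),
            "constitutive_equation": self.equation.to_dict(),
            "type": str(self.type_label),
            "type_trace": {
                "/".join(map(str, path)) or ".": str(label)
                for path, label in sorted(self.trace.node_labels.items())
            },
            "first_unidentifiable_join": (
                self.trace.first_u.describe(self._node_at(self.trace.first_u.path))
                if self.trace.first_u
                else None
            ),
            "local": self.local.to_dict(),
            "global": self.global_.to_dict(),
            "nonmonic_coefficients": [
                {"label": lbl, "expression": expr} for lbl, expr in self.coefficients
            ],
            "warnings": list(self.warnings),
        }
        if self.oracle is not None:
            d["oracle"] = self.oracle
        return d

    def _node_at(self, path: tuple) -> Network:
        node = self.network
        for i in path:
            node = node.children[i]
        return node

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self, verbose: bool = False) -> str:
        lines = [
            f"network:    {self.network.serialize()}",
            f"equation:   {self.equation.pretty()}",
            f"shapes:     P {self.equation.p_shape}  Q {self.equation.q_shape}",
            f"type:       {self.type_label}",
            f"local:      {self.local.status} "
            f"({self.local.n_params} parameters, "
            f"{self.local.n_nonmonic} non-monic coefficients)",
            f"global:     {self.global_.status}",
        ]
        if self.global_.construction_order:
            steps = ", ".join(
                p if how == "seed" else f"{p} ({how})"
                for p, how in self.global_.construction_order
            )
            lines.append(f"build:      {steps}")
        elif not self.global_.constructible:
            lines.append(
                "build:      not constructible one element at a time "
                "(an internal node carries two composite branches)"
            )
        if self.trace.first_u is not None:
            node = self._node_at(self.trace.first_u.path)
            lines.append(f"failure:    {self.trace.first_u.describe(node)}")
        if verbose:
            lines.append("trace:")
            for path, label in sorted(self.trace.node_labels.items()):
                loc = "/".join(map(str, path)) or "(root)"
                lines.append(f"  {loc}: {label}")
            lines.append("coefficients:")
            for lbl, expr in self.coefficients:
                lines.append(f"  {lbl} = {expr}")
        if self.oracle is not None:
            for key, value in self.oracle.items():
                lines.append(f"oracle:     {key} = {value}")
        for w in self.warnings:
            lines.append(f"warning:    {w}")
        return "\n".join(lines)


def analyze(
    net: Network,
    input_text: str = "",
    run_oracles: bool = False,
    seed: int = 0,
    n_starts: int = 200,
    warnings_: list | None = None,
    evaluator: GenericEvaluator | None = None,
) -> AnalysisReport:
    """Run the full decision procedure on a network and assemble the report."""
    evaluator = evaluator or GenericEvaluator(seed)
    eq = derive_constitutive(net, normalized=True, evaluator=evaluator)
    label, trace = tau(net)
    gv = global_identifiability(net, evaluator)
    cmap = coefficient_map(net, evaluator)
    coeffs = tuple(
        (lbl, str(expr)) for lbl, expr in zip(cmap.labels, cmap.entries)
    )
    oracle = None
    if run_oracles:
        oracle = {
            "jacobian_rank": jacobian_rank_oracle(net, seed=seed),
            "n_params": gv.local.n_params,
        }
        if gv.local.identifiable and gv.local.n_params <= 8:
            oracle["preimage_count"] = preimage_count_oracle(
                net, seed=seed, n_starts=n_starts
            )
    return AnalysisReport(
        input_text=input_text or net.serialize(),
        network=net,
        equation=eq,
        type_label=label,
        trace=trace,
        local=gv.local,
        global_=gv,
        coefficients=coeffs,
        oracle=oracle,
        warnings=list(warnings_ or []),
    )
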