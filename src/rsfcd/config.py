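"""Configuration schema, validation and (de)serialization.

The full model configuration is a nested document (YAML or JSON) with
blocks ``receptor.membrane`` / ``receptor.cytoplasmic``, ``phospho``,
``methylation``, ``flagellar``, ``variant``, ``mutations`` and ``solver``.
Any omitted block is defaulted; a config naming only ``variant`` is valid.
Model III defaults its receptor cooperativity to the constant cluster size
17.5 unless given explicitly.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import pathway
from .pathway import (ChemotaxisModel, FlagellarParams, MethylationParams,
                      ModelVariant, PhosphoNetworkParams, SolverOptions)
from .receptors import ReceptorClusterParams

__all__ = ["ReceptorBlock", "ModelConfig", "load_config", "dump_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReceptorBlock(_Block):
    N: float = Field(6.0, gt=0)
    alpha: float = Field(2.0, gt=0)
    m0: float = 5.0
    K_A_uM: float = Field(3000.0, gt=0)
    K_I_uM: float = Field(18.0, gt=0)

    @model_validator(mode="after")
    def _ordering(self) -> "ReceptorBlock":
        if not self.K_A_uM > self.K_I_uM:
            raise ValueError(
                f"K_A_uM must exceed K_I_uM (got {self.K_A_uM} <= {self.K_I_uM})")
        return self

    def to_params(self) -> ReceptorClusterParams:
        return ReceptorClusterParams(N=self.N, alpha=self.alpha, m0=self.m0,
                                     K_A=self.K_A_uM, K_I=self.K_I_uM)


class ReceptorsBlock(_Block):
    membrane: Optional[ReceptorBlock] = None
    cytoplasmic: Optional[ReceptorBlock] = None


class PhosphoBlock(_Block):
    totals: dict = Field(default_factory=pathway._default_totals)
    k_auto_A2: float = Field(10.0, ge=0)
    k_auto_A34: float = Field(10.0, ge=0)
    k_transfer: dict = Field(default_factory=pathway._default_transfer)
    k_dephos: dict = Field(default_factory=pathway._default_dephos)
    R2: float = Field(1.0, ge=0)
    R3: float = Field(1.0, ge=0)

    def to_params(self) -> PhosphoNetworkParams:
        return PhosphoNetworkParams(
            totals=pathway._default_totals() | self.totals,
            k_auto_A2=self.k_auto_A2, k_auto_A34=self.k_auto_A34,
            k_transfer=pathway._default_transfer() | self.k_transfer,
            k_dephos=pathway._default_dephos() | self.k_dephos,
            R2=self.R2, R3=self.R3)


class MethylationBlock(_Block):
    k_R: float = Field(0.01, gt=0)
    k_Rt: float = Field(0.01, gt=0)
    k_B1: float = Field(0.01, ge=0)
    k_B2: float = Field(0.01, ge=0)
    k_B2t: float = Field(0.01, ge=0)

    def to_params(self) -> MethylationParams:
        return MethylationParams(**self.model_dump())


class FlagellarBlock(_Block):
    f_max: float = Field(8.0, gt=0)
    q: float = Field(64.0, gt=0)
    hill_n: float = Field(4.0, gt=0)

    def to_params(self) -> FlagellarParams:
        return FlagellarParams(f_max=self.f_max, q=self.q, hill_n=self.hill_n)


class SolverBlock(_Block):
    method: str = "LSODA"
    rtol: float = Field(1e-10, gt=0)
    atol: float = Field(1e-12, gt=0)
    max_step: float = Field(math.inf, gt=0)

    def to_params(self) -> SolverOptions:
        return SolverOptions(**self.model_dump())


class ModelConfig(_Block):
    """Validated full configuration of one pathway model."""

    variant: str = "I"
    tau_Lt: float = Field(10.0, gt=0)
    mutations: list = Field(default_factory=list)
    receptor: ReceptorsBlock = Field(default_factory=ReceptorsBlock)
    phospho: PhosphoBlock = Field(default_factory=PhosphoBlock)
    methylation: MethylationBlock = Field(default_factory=MethylationBlock)
    flagellar: FlagellarBlock = Field(default_factory=FlagellarBlock)
    activity_form: str = "exact"
    methylation_leak: float = Field(0.0, ge=0)
    solver: SolverBlock = Field(default_factory=SolverBlock)

    @field_validator("variant")
    @classmethod
    def _variant(cls, v: str) -> str:
        if v not in ("I", "II", "III"):
            raise ValueError(f"variant must be one of I, II, III (got {v!r})")
        return v

    @field_validator("activity_form")
    @classmethod
    def _form(cls, v: str) -> str:
        if v not in ("exact", "log"):
            raise ValueError(f"activity_form must be 'exact' or 'log' (got {v!r})")
        return v

    @field_validator("mutations")
    @classmethod
    def _mutations(cls, v: list) -> list:
        bad = set(v) - set(pathway.MUTATIONS)
        if bad:
            raise ValueError(f"unknown mutations {sorted(bad)}; "
                             f"known: {pathway.MUTATIONS}")
        return v

    def build(self) -> ChemotaxisModel:
        default_N = 17.5 if self.variant == "III" else 6.0
        mem = (self.receptor.membrane or ReceptorBlock(N=default_N)).to_params()
        cyt = (self.receptor.cytoplasmic or ReceptorBlock(N=default_N)).to_params()
        variant = ModelVariant(id=self.variant, tau_Lt=self.tau_Lt,
                               mutations=frozenset(self.mutations))
        return ChemotaxisModel(
            variant=variant, membrane=mem, cytoplasmic=cyt,
            phospho=self.phospho.to_params(),
            methylation=self.methylation.to_params(),
            flagellar=self.flagellar.to_params(),
            activity_form=self.activity_form,
            methylation_leak=self.methylation_leak,
            solver=self.solver.to_params())

    def content_hash(self) -> str:
        """Stable hash of the semantic content (for run manifests)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    return ModelConfig.model_validate(raw)


def dump_config(cfg: ModelConfig, path=None) -> str:
    """Serialize a configuration to YAML; round-trips through load_config."""
    doc = cfg.model_dump(exclude_none=True)
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
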