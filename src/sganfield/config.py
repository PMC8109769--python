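"""Run configuration models.

``GanConfig`` collects every knob of the adversarial classifier.  The
defaults mirror the full-scale setup (448x448 images, 512-channel generator
reshape, batch 30, Adam at 1e-4 with beta1 0.8 and weight decay 5e-4);
:meth:`GanConfig.desk_profile` is the scaled-down profile used for CPU-scale
experiments on synthetic imagery.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError

UPSAMPLE_STAGES = 4  # generator doubles the spatial side this many times


class GanConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    base: int = Field(28, ge=2, description="generator reshape side; image side = base * 16")
    latent_dim: int = Field(100, ge=1)
    n_real_classes: int = Field(2, ge=2)
    gen_width: int = Field(512, ge=8, description="channels at the generator reshape; halves per stage")
    disc_width: int = Field(64, ge=4, description="channels of the first discriminator block")
    gen_kernel: int = 5
    disc_kernel: int = 3
    lr_g: float = Field(1e-4, gt=0)
    lr_d: float = Field(1e-4, gt=0)
    beta1: float = Field(0.8, ge=0, lt=1)
    beta2: float = Field(0.999, ge=0, lt=1)
    weight_decay: float = Field(5e-4, ge=0)
    batch_size: int = Field(30, ge=2)
    epochs: int = Field(1000, ge=1)
    seed: int = 0
    grad_clip: float = Field(5.0, ge=0, description="global gradient-norm cap; 0 disables")
    dropout: float = Field(0.3, ge=0, lt=1)
    leaky_slope: float = Field(0.2, ge=0)
    include_labeled_in_unsupervised: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.batch_size % 2 != 0:
            raise ConfigurationError(
                f"batch_size must be even (it is split in halves when training G), got {self.batch_size}"
            )
        if self.gen_width % 8 != 0:
            raise ConfigurationError("gen_width must be divisible by 8 (channels halve over four stages)")
        return self

    @property
    def image_side(self) -> int:
        return self.base * 2 ** UPSAMPLE_STAGES

    @classmethod
    def desk_profile(cls, **overrides) -> "GanConfig":
        """64x64 images, narrow nets, 150 epochs: a CPU-scale training profile."""
        defaults = dict(base=4, gen_width=64, disc_width=8, epochs=150, lr_d=1e-3, lr_g=2e-4)
        defaults.update(overrides)
        return cls(**defaults)
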