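"""Compare the plain U-Net block with the depthwise-separable residual one.

The separable block cuts the parameter count several-fold; the identity
residual shortcut adds exactly zero parameters. Full training ladders
(with accuracies) are available via `hsiseg experiment --name e1|e2|e3`.
"""

from hsiseg import (
    NetConfig,
    build_dual_branch,
    build_plain_unet,
    build_single_branch,
    count_parameters,
)

cfg = dict(n_classes=5)
plain = build_plain_unet(NetConfig(**cfg))
ours = build_single_branch(NetConfig(**cfg))
no_res = build_single_branch(NetConfig(residual=False, **cfg))
dual = build_dual_branch(NetConfig(branch_mode="dual", **cfg))

rows = [
    ("plain U-Net (3x3 convs)", plain),
    ("separable + residual", ours),
    ("separable, residual off", no_res),
    ("dual-branch separable", dual),
]
for name, model in rows:
    print(f"{name:28s} {count_parameters(model) / 1e6:7.3f} M")
print()
print("residual toggle parameter delta:",
      count_parameters(ours) - count_parameters(no_res))
print(f"plain / separable ratio: "
      f"{count_parameters(plain) / count_parameters(ours):.2f}x")
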