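# Units

All quantities use a millimetre–second system unless a name says otherwise.

| Quantity | Symbol | Unit |
| --- | --- | --- |
| Positions, radii, distances | x, y, ρ, δ | mm |
| Angles (body angle, headings, θ) | α, θ | rad, wrapped to (−π, π] |
| Curvature | κ | mm⁻¹ (signed; positive = center of curvature right of the head direction) |
| Time | t, τ, τ_b, λ | s |
| Speeds | u, v_f | mm/s |
| Volumetric flow rate | Q_v | mm³/s (0.22 mL/s = 220 mm³/s) |
| Surfacic flow rate | q = Q_v/(2πh) | mm²/s |
| Water depth | h | mm |
| Frame rate | — | Hz |
| Pixel size | — | mm/pixel (nominal 0.035) |
| Segmentation blur box / σ | — | µm (converted to pixels internally) |
| Blob areas | — | pixels |
| Intensities | — | arbitrary camera units (uint16 frames) |

Column-name suffixes in CSV outputs state the unit (`_mm`, `_s`, `_rad`,
`_per_mm`, `_mm_s`).  The arena origin is the field-of-view corner given in
`FlowConfig.fov`; the suction point is at `FlowConfig.sink`.
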