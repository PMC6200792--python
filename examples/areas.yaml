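# Global ecosystem extents for upscaling (user-supplied inputs, never
# bundled as facts).  Each entry carries the extent in m² and a note on
# where it comes from.
lake:
  # 5.0e6 km²: global lake + pond surface area consistent with
  # inventory-based estimates; also back-computes a 78 Tg C y⁻¹ global
  # flux at a 15.6 g C m⁻² y⁻¹ mean rate.
  area_m2: 5.0e12
  citation: "global lake area inventory (user to confirm against current literature)"
mangrove:
  # 1.6e5 km²: approximate global mangrove forest extent; back-computes
  # an 11.7 Tg C y⁻¹ global flux at a 73.2 g C m⁻² y⁻¹ mean rate.
  area_m2: 1.6e11
  citation: "global mangrove extent (user to confirm against current literature)"
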