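# Diet presets: diet-exchange id (or base metabolite id) -> [lower, upper]
# flux bounds in model units (mmol/gDW/h).  Negative lower bound = uptake
# allowed into the lumen.
#
# "western-toy" is the diet the bundled toy fixtures are built around:
# glucose for the host route and a peptone (amino-acid) substrate that
# supports baseline microbial growth, so the system stays viable even when
# microbial secretion is capped or no prebiotic is supplied.
western-toy:
  bounds:
    glc: [-3.0, 0.0]
    aa: [-1.0, 0.0]
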