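# Shipped stain profiles for chromogenic positive-pixel classification.
# Hues are fractions of the color circle (red = 0).  The trichrome blue and
# DAB profiles use the classic positive-pixel-count default hue width (0.5,
# which accepts every hue and leaves discrimination to saturation); PAS uses
# a narrow width so only basement-membrane magenta is counted; the trichrome
# red (Biebrich scarlet) width excludes the aniline blue on the same slide.
trichrome_blue:
  hue_center: 0.60
  hue_width: 0.50
trichrome_red:
  hue_center: 0.96
  hue_width: 0.20
pas:
  hue_center: 0.86
  hue_width: 0.05
collagen_iii:
  hue_center: 0.10
  hue_width: 0.50
cytokeratin:
  hue_center: 0.10
  hue_width: 0.50
cd34:
  hue_center: 0.10
  hue_width: 0.50
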