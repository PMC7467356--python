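# Default IgG Fc glycopeptide panel: 20 glycoforms per subclass.
#
# Notation GxFNSk: x antennary galactoses, F = core fucose, N = bisecting
# GlcNAc, Sk = k sialic acids (NeuAc).  hex counts the 3 core mannoses plus
# galactoses; hexnac the 4 core GlcNAc plus the bisecting GlcNAc.
# This file is data: edit or replace it to change the panel.
glycoforms:
  - {label: G0,     hex: 3, hexnac: 4, dhex: 0, neuac: 0}
  - {label: G1,     hex: 4, hexnac: 4, dhex: 0, neuac: 0}
  - {label: G2,     hex: 5, hexnac: 4, dhex: 0, neuac: 0}
  - {label: G0N,    hex: 3, hexnac: 5, dhex: 0, neuac: 0}
  - {label: G1N,    hex: 4, hexnac: 5, dhex: 0, neuac: 0}
  - {label: G2N,    hex: 5, hexnac: 5, dhex: 0, neuac: 0}
  - {label: G0F,    hex: 3, hexnac: 4, dhex: 1, neuac: 0}
  - {label: G1F,    hex: 4, hexnac: 4, dhex: 1, neuac: 0}
  - {label: G2F,    hex: 5, hexnac: 4, dhex: 1, neuac: 0}
  - {label: G0FN,   hex: 3, hexnac: 5, dhex: 1, neuac: 0}
  - {label: G1FN,   hex: 4, hexnac: 5, dhex: 1, neuac: 0}
  - {label: G2FN,   hex: 5, hexnac: 5, dhex: 1, neuac: 0}
  - {label: G1S1,   hex: 4, hexnac: 4, dhex: 0, neuac: 1}
  - {label: G2S1,   hex: 5, hexnac: 4, dhex: 0, neuac: 1}
  - {label: G2S2,   hex: 5, hexnac: 4, dhex: 0, neuac: 2}
  - {label: G1FS1,  hex: 4, hexnac: 4, dhex: 1, neuac: 1}
  - {label: G2FS1,  hex: 5, hexnac: 4, dhex: 1, neuac: 1}
  - {label: G2FS2,  hex: 5, hexnac: 4, dhex: 1, neuac: 2}
  - {label: G1FNS1, hex: 4, hexnac: 5, dhex: 1, neuac: 1}
  - {label: G2FNS1, hex: 5, hexnac: 5, dhex: 1, neuac: 1}
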