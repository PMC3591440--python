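>NOX5_LIKE_SYNTHETIC synthetic NOX5-like construct: four canonical EF-hand loops fused to the NOX2 core (not UniProtKB Q96PH1)
MSAELAQKDKDGDGTITTKEAQLSEEALRKLAEKFKALDADGNGTIDFPEAQLSEEALRK
LAEKFKALDKDGNGYISAAEAQLSEEALRKLAEKFKALDIDGDGQVNYEEAQLSEEALRK
LAEKFKALGNWAVNEGLSIFVILVWLGLNVFLFVWYYRVYDIPPKFFYTRKLLGSALALA
RAPAACLNFNCMLILLPVCRNLLSFLRGSSACCSTRVRRQLDRNLTFHKMVAWMIALHSA
IHTIAHLFNVEWCVNARVNNSDPYSVALSELGDRQNESYLNFARKRIKNPEGGLYLAVTL
LAGITGVVITLCLILIITSSTKTIRRSYFEVFWYTHHLFVIFFIGLAIHGAERIVRGQTA
ESLAVHNITVCEQKISEWGKIKECPIPQFAGNPPMTWKWIVGPMFLYLCERLVRFWRSQQ
KVVITKVVTHPFKTIELQMKKKGFKMEVGQYIFVKCPKVSKLEWHPFTLTSAPEEDFFSI
HIRIVGDWTEGLFNACGCDKQEFQDAWKLPKIAVDGPFGTASEDVFSYEVVMLVGAGIGV
TPFASILKSVWYKYCNNATNLKLKKIYFYWLCRDTHAFEWFADLLQLLESQMQERNNAGF
LSYNIYLTGWDESQANHFAVHHDEEKDVITGLKQKTLYGRPNWDNEFKTIASQHPNTRIG
VFLCGPEALAETLSKQSISNSESGPRGVHFIFNKENF
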