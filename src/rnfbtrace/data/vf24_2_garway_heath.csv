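id,x_deg,y_deg,sector
p01,-9,21,IT
p02,-3,21,IT
p03,3,21,IN
p04,9,21,IN
p05,-15,15,IT
p06,-9,15,IT
p07,-3,15,IT
p08,3,15,IN
p09,9,15,IN
p10,15,15,IN
p11,-21,9,IT
p12,-15,9,IT
p13,-9,9,IT
p14,-3,9,IT
p15,3,9,IT
p16,9,9,IN
p17,15,9,IN
p18,21,9,N
p19,-27,3,IT
p20,-21,3,IT
p21,-15,3,IT
p22,-9,3,IT
p23,-3,3,IT
p24,3,3,T
p25,9,3,T
p26,21,3,N
p27,-27,-3,ST
p28,-21,-3,ST
p29,-15,-3,ST
p30,-9,-3,ST
p31,-3,-3,ST
p32,3,-3,T
p33,9,-3,T
p34,21,-3,N
p35,-21,-9,ST
p36,-15,-9,ST
p37,-9,-9,ST
p38,-3,-9,ST
p39,3,-9,ST
p40,9,-9,SN
p41,15,-9,SN
p42,21,-9,N
p43,-15,-15,ST
p44,-9,-15,ST
p45,-3,-15,ST
p46,3,-15,SN
p47,9,-15,SN
p48,15,-15,SN
p49,-9,-21,ST
p50,-3,-21,ST
p51,3,-21,SN
p52,9,-21,SN
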