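id	species	role
HYC-10(T)	B. xiamenensis	train
B4133	B. altitudinis	test
C772	B. altitudinis	train
INR7	B. altitudinis	test
B-388	B. altitudinis	train
LAMA 585	B. altitudinis	train
MTCC B6033	B. altitudinis	test
41KF2b(T)	B. altitudinis	train
BA06	B. altitudinis	test
S-1	B. altitudinis	test
B4129	B. safensis	test
S9	B. safensis	train
WP8	B. safensis	test
FO-36b(T)	B. safensis	train
B4134	B. safensis	test
B4107	B. safensis	test
CCMA-560	B. safensis	test
VK	B. safensis	train
CFA06	B. safensis	train
Fairview	B. safensis	test
7P	B. pumilus	test
SAFR-032	B. pumilus	train
ATCC 7061(T)	B. pumilus	train
B4127	B. pumilus	test
FZB42(T)	B. amyloliquefaciens	-
168(T)	B. subtilis	-
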