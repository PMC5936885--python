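word_id	transcription	part_of_speech	slot
n01	ʤìíʔ^j^ò	noun	name
n02	bàúnè	noun	name
n03	káúʦì	noun	name
n04	nèèpáh^j^ù	noun	name
n05	mòòkúnè	noun	name
n06	tééβák^j^à	noun	name
n07	òʔʣíβà	noun	name
n08	èhkúrà	noun	name
n09	áhtúmè	noun	name
n10	mànúrì	noun	name
n11	kòtámè	noun	name
n12	pátúkè	noun	name
n13	bàtíhrò	noun	name
n14	dáβéhnù	noun	name
n15	mééróhʦà	noun	name
n16	nééβúhpà	noun	name
n17	βéhtáhkò	noun	name
n18	góʔpáʔtè	noun	name
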