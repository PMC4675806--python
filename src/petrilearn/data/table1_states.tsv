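A	AP	B	BP
<zer,pos>	<pos,neg>	<pos,neg>	<pos,neg>
<pos,pos>	<pos,pos>	<zer,pos>	<pos,neg>
<pos,zer>	<pos,zer>	<pos,neg>	<pos,neg>
<pos,pos>	<pos,pos>	<pos,neg>	<pos,neg>
<pos,neg>	<zer,pos>	<pos,neg>	<pos,neg>
<zer,pos>	<pos,neg>	<pos,zer>	<pos,neg>
<pos,zer>	<pos,neg>	<pos,zer>	<pos,neg>
<pos,neg>	<pos,zer>	<pos,zer>	<pos,neg>
<pos,zer>	<pos,zer>	<pos,zer>	<pos,neg>
<pos,neg>	<pos,pos>	<pos,zer>	<pos,neg>
<zer,zer>	<zer,zer>	<zer,zer>	<zer,zer>
<pos,pos>	<pos,zer>	<zer,zer>	<zer,zer>
<pos,pos>	<pos,zer>	<pos,zer>	<pos,zer>
<pos,pos>	<pos,neg>	<pos,pos>	<pos,zer>
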