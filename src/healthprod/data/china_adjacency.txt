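# Queen-style land-border contiguity among the 31 mainland Chinese
# provincial units, plus the HaiNan-GuangDong sea link (Geoda community
# convention) so that no unit is an island. One undirected edge per line.
BeiJing	TianJin
BeiJing	HeBei
TianJin	HeBei
HeBei	ShanXi
HeBei	NeiMengGu
HeBei	LiaoNing
HeBei	ShanDong
HeBei	HeNan
ShanXi	NeiMengGu
ShanXi	ShaanXi
ShanXi	HeNan
NeiMengGu	ShaanXi
NeiMengGu	NingXia
NeiMengGu	GanSu
NeiMengGu	LiaoNing
NeiMengGu	JiLin
NeiMengGu	HeiLongJiang
LiaoNing	JiLin
JiLin	HeiLongJiang
ShangHai	JiangSu
ShangHai	ZheJiang
JiangSu	ZheJiang
JiangSu	AnHui
JiangSu	ShanDong
ZheJiang	AnHui
ZheJiang	JiangXi
ZheJiang	FuJian
AnHui	JiangXi
AnHui	HuBei
AnHui	HeNan
AnHui	ShanDong
FuJian	JiangXi
FuJian	GuangDong
JiangXi	GuangDong
JiangXi	HuNan
JiangXi	HuBei
ShanDong	HeNan
HeNan	ShaanXi
HeNan	HuBei
HuBei	ShaanXi
HuBei	ChongQing
HuBei	HuNan
HuNan	GuangDong
HuNan	GuangXi
HuNan	GuiZhou
HuNan	ChongQing
GuangDong	GuangXi
GuangDong	HaiNan
GuangXi	GuiZhou
GuangXi	YunNan
ChongQing	ShaanXi
ChongQing	GuiZhou
ChongQing	SiChuan
SiChuan	GuiZhou
SiChuan	YunNan
SiChuan	XiZang
SiChuan	QingHai
SiChuan	GanSu
SiChuan	ShaanXi
GuiZhou	YunNan
YunNan	XiZang
XiZang	XinJiang
XiZang	QingHai
ShaanXi	GanSu
ShaanXi	NingXia
GanSu	XinJiang
GanSu	QingHai
GanSu	NingXia
QingHai	XinJiang
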